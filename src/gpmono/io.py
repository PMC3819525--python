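"""File formats, run manifests and the batch pipeline.

GP maps travel as CSV (``genotype,value`` with genotype strings like
"1211"; any row order, full 3**N coverage required) or as JSON
(``{"n_loci": N, "values": [...]}`` in canonical order).  All floating
point output uses 12 significant digits so that repeated runs with one
seed produce byte-identical tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import motifs as motifs_mod
from .gpmap import GPMap, genotype_index, label_to_counts
from .grn import SimConfig, monte_carlo_study

__all__ = [
    "GPMapFormatError",
    "read_gpmap",
    "write_gpmap",
    "RunManifest",
    "run_pipeline",
]

FLOAT_FMT = "%.12g"


class GPMapFormatError(ValueError):
    """Malformed GP map file (bad genotype string, coverage, or value)."""


def _package_version() -> str:
    try:
        return metadata.version("gpmono")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def read_gpmap(path) -> GPMap:
    """Read a GP map from CSV or JSON; rows are reordered canonically."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        try:
            return GPMap(n_loci=int(doc["n_loci"]), values=np.asarray(doc["values"], float))
        except (KeyError, ValueError) as exc:
            raise GPMapFormatError(f"{path}: {exc}") from exc
    df = pd.read_csv(path, dtype={"genotype": str})
    if not {"genotype", "value"} <= set(df.columns):
        raise GPMapFormatError(f"{path}: need columns 'genotype' and 'value'")
    first = str(df["genotype"].iloc[0]) if len(df) else ""
    n_loci = len(first) // 2
    if n_loci < 1:
        raise GPMapFormatError(f"{path}: empty or malformed genotype column")
    values = np.full(3**n_loci, np.nan)
    seen = set()
    for row_number, (label, value) in enumerate(
        zip(df["genotype"], df["value"]), start=2
    ):
        label = str(label)
        if len(label) != 2 * n_loci:
            raise GPMapFormatError(
                f"{path}: genotype {label!r} has wrong length (row {row_number})"
            )
        try:
            idx = genotype_index(label_to_counts(label))
        except ValueError as exc:
            raise GPMapFormatError(f"{path}: {exc} (row {row_number})") from exc
        if idx in seen:
            raise GPMapFormatError(f"{path}: duplicate genotype {label!r}")
        seen.add(idx)
        value = pd.to_numeric(value, errors="coerce")
        if pd.isna(value):
            raise GPMapFormatError(
                f"{path}: non-numeric value for genotype {label!r} (row {row_number})"
            )
        values[idx] = float(value)
    missing = np.flatnonzero(np.isnan(values))
    if missing.size:
        gm = GPMap(n_loci=n_loci, values=np.zeros(3**n_loci))
        raise GPMapFormatError(
            f"{path}: missing genotype {gm.labels[missing[0]]!r}"
        )
    return GPMap(n_loci=n_loci, values=values)


def write_gpmap(gpmap: GPMap, path) -> None:
    """Write a GP map as canonical-order CSV (or JSON by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {"n_loci": gpmap.n_loci, "values": [float(v) for v in gpmap.values]}
        path.write_text(json.dumps(doc, indent=1) + "\n")
        return
    df = pd.DataFrame({"genotype": gpmap.labels, "value": gpmap.values})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


@dataclass
class RunManifest:
    """Deterministic record of one pipeline run."""

    command: str
    seed: int
    config: dict
    version: str = field(default_factory=_package_version)
    counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "command": self.command,
                "seed": self.seed,
                "version": self.version,
                "config": self.config,
                "counts": self.counts,
            },
            indent=1,
            sort_keys=True,
        )


def _quantiles(values) -> dict:
    arr = np.asarray([v for v in values if not math.isnan(v)], float)
    if arr.size == 0:
        return {"q25": math.nan, "median": math.nan, "q75": math.nan, "mean": math.nan}
    q25, med, q75 = np.quantile(arr, [0.25, 0.5, 0.75])
    return {
        "q25": float(q25),
        "median": float(med),
        "q75": float(q75),
        "mean": float(arr.mean()),
    }


def summarize_results(results, motif_rows) -> pd.DataFrame:
    """Per-motif summary table from Monte-Carlo results.

    motif_rows: DataFrame rows of the motif table aligned with results.
    """
    records = []
    for res, (_, mrow) in zip(results, motif_rows.iterrows()):
        rec = dict(mrow)
        rec.update(
            n_reps=res.n_reps,
            usable=res.usable,
            discarded_nonconvergence=res.discarded_nonconv,
            discarded_flat=res.discarded_flat,
            included=res.included,
        )
        for i in range(4):
            rec[f"order_breaking_{i}"] = int(res.order_breaking_hist[i])
        for prefix, vals in (
            ("m", res.m_values),
            ("r2_mono", res.r2_values),
            ("va_vg", res.va_vg_values),
        ):
            for stat, v in _quantiles(vals).items():
                rec[f"{prefix}_{stat}"] = v
        records.append(rec)
    return pd.DataFrame.from_records(records)


def run_pipeline(config: dict, out_dir) -> RunManifest:
    """Enumerate motifs, simulate GP maps, and score them, per config.

    Config keys: ``seed`` (root seed for all randomness); ``simulate``
    (optional) with ``pleiotropy``, ``n_reps``, ``n_motifs``,
    ``motif_class`` (restrict to one class label) or ``motif_ids``
    (explicit rows of the motif table), and ``write_maps``.  Outputs
    ``motifs.csv``, optionally ``motif_summary.csv`` plus per-replicate
    maps, and ``manifest.json``; identical config + seed gives
    byte-identical tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(command="run_pipeline", seed=seed, config=config)

    table = motifs_mod.motif_table()
    table.to_csv(out / "motifs.csv", index=False, float_format=FLOAT_FMT)
    manifest.counts["motifs_enumerated"] = 6859
    manifest.counts["motifs_after_downstream_filter"] = 3724
    manifest.counts["motif_representatives"] = len(table)

    sim_cfg = config.get("simulate")
    if sim_cfg:
        sel = table
        if "motif_ids" in sim_cfg:
            sel = table.loc[table["motif_id"].isin(sim_cfg["motif_ids"])]
        elif "motif_class" in sim_cfg:
            sel = table.loc[table["motif_class"] == sim_cfg["motif_class"]]
        n_motifs = sim_cfg.get("n_motifs")
        if n_motifs is not None:
            # spawn key 7 reserves a stream distinct from replicate streams
            picker = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(7,))
            )
            chosen = picker.choice(len(sel), size=min(n_motifs, len(sel)), replace=False)
            sel = sel.iloc[np.sort(chosen)]
        scfg = SimConfig(
            pleiotropy=bool(sim_cfg.get("pleiotropy", False)),
            n_reps=int(sim_cfg.get("n_reps", 1000)),
            seed=seed,
        )
        matrices = [
            np.array(
                [[row[f"A{k + 1}{l + 1}"] for l in range(3)] for k in range(3)], int
            )
            for _, row in sel.iterrows()
        ]
        keep = bool(sim_cfg.get("write_maps", False))
        results = monte_carlo_study(matrices, scfg, keep_maps=keep)
        for res, mid in zip(results, sel["motif_id"]):
            res.motif_id = int(mid)
        summary = summarize_results(results, sel)
        summary.to_csv(out / "motif_summary.csv", index=False, float_format=FLOAT_FMT)
        if keep:
            maps_dir = out / "gpmaps"
            maps_dir.mkdir(exist_ok=True)
            for res in results:
                for j, gm in enumerate(res.gpmaps):
                    write_gpmap(gm, maps_dir / f"motif{res.motif_id}_rep{j}.csv")
        manifest.counts["replicates_run"] = int(sum(r.n_reps for r in results))
        manifest.counts["replicates_usable"] = int(sum(r.usable for r in results))
        manifest.counts["replicates_discarded_nonconvergence"] = int(
            sum(r.discarded_nonconv for r in results)
        )
        manifest.counts["replicates_discarded_flat"] = int(
            sum(r.discarded_flat for r in results)
        )
        manifest.counts["motifs_simulated"] = len(results)
        manifest.counts["motifs_included"] = int(sum(r.included for r in results))
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
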