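"""Batch cavity surveys: per-structure records, TSV output, and aggregates.

One record per (structure, chain selection): volumes, closure fraction,
pocket/cavity label, and all shell descriptors, plus a parameter fingerprint
so every number is traceable to the lattice constant, probe radius, rotation
count, seed, and radii table that produced it.  Summaries recompute the
pocket threshold (mean s minus three standard deviations) from the batch and
histogram the shell hydropathy H.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cavity import run_spaceball
from .descriptors import compute_descriptors
from .lattice import ProbeParams
from .structure import Structure, StructureError, read_structure
from .surface import POCKET_THRESHOLD, compute_surface_metrics
from .tables import VDW_RADII, table_fingerprint

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "id", "chains", "status", "v_t_nm3", "v_c_nm3", "v_c_std_nm3", "v_c_over_v_t",
    "n_chambers", "s_c_nm2", "s_cp_nm2", "s", "label", "n_cp", "H", "h_norm",
    "H_per_residue", "r_g", "r1", "r2", "r3", "w", "n_entrances", "fingerprint",
]

# Table-style precision: volumes/areas 2 dp, s and w 2 dp, radii 2 dp, H 1 dp.
_FORMATS = {
    "v_t_nm3": 2, "v_c_nm3": 2, "v_c_std_nm3": 2, "v_c_over_v_t": 3,
    "s_c_nm2": 2, "s_cp_nm2": 2, "s": 2, "H": 1, "h_norm": 1,
    "H_per_residue": 2, "r_g": 2, "r1": 2, "r2": 2, "r3": 2, "w": 2,
}


def entry_seed(base_seed: int, structure_id: str) -> int:
    """Per-entry seed: base seed plus a stable hash of the id (< 2^31)."""
    return (int(base_seed) + zlib.crc32(structure_id.encode())) % (2**31 - 1)


def analyze_structure(
    structure: Structure,
    params: ProbeParams,
    threshold: float = POCKET_THRESHOLD,
    radii_table: Mapping[str, float] | None = None,
) -> dict:
    """Run the full pipeline on one structure and return a flat record."""
    result = run_spaceball(structure, params)
    metrics = compute_surface_metrics(result, threshold)
    desc = compute_descriptors(metrics, result.rotated_structure)
    ref = result.rotations[result.reference_rotation]
    v_t = result.v_t_mean
    record = {
        "id": structure.id,
        "chains": ",".join(structure.chains()),
        "status": "ok",
        "v_t_nm3": v_t,
        "v_c_nm3": result.v_c_mean,
        "v_c_std_nm3": result.v_c_std,
        "v_c_over_v_t": result.v_c_mean / v_t if v_t > 0 else None,
        "n_chambers": ref.n_chambers,
        "s_c_nm2": metrics.s_c,
        "s_cp_nm2": metrics.s_cp,
        "s": metrics.s,
        "label": metrics.label,
        "n_cp": desc.n_cp,
        "H": desc.h,
        "h_norm": desc.h_norm,
        "H_per_residue": desc.h_per_residue,
        "r_g": desc.r_g,
        "r1": desc.radii[0] if desc.radii else None,
        "r2": desc.radii[1] if desc.radii else None,
        "r3": desc.radii[2] if desc.radii else None,
        "w": desc.w,
        "n_entrances": int(len(result.entrances)),
        "fingerprint": _fingerprint(params, radii_table),
    }
    return record


def _fingerprint(params: ProbeParams, radii_table: Mapping[str, float] | None) -> str:
    table = radii_table if radii_table is not None else VDW_RADII
    p = params.fingerprint()
    return (
        f"a={p['a']};r_w={p['r_w']};rot={p['n_rotations']};seed={p['seed']};"
        f"radii={table_fingerprint(table)}"
    )


def read_manifest(path: str | Path) -> list[tuple[str, str | None]]:
    """Read a TSV manifest of ``path<TAB>chains`` (chains optional)."""
    entries: list[tuple[str, str | None]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        entries.append((parts[0], parts[1] if len(parts) > 1 and parts[1] else None))
    if not entries:
        raise ValueError(f"empty manifest: {path}")
    return entries


def run_survey(
    manifest: Sequence[tuple[str, str | None]],
    params: ProbeParams,
    threshold: float = POCKET_THRESHOLD,
    radii_table: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """One record per manifest entry; failures become rows, never aborts.

    Each entry runs with its own seed derived from the base seed and a stable
    hash of the entry id, so results are independent of manifest order and
    individually reproducible.
    """
    if not manifest:
        raise ValueError("empty manifest")
    rows = []
    for path, chains in manifest:
        entry_id = Path(path).stem + (f":{chains}" if chains else "")
        try:
            st = read_structure(path, chains=chains, radii_table=radii_table)
            p = dataclasses.replace(params, seed=entry_seed(params.seed, entry_id))
            row = analyze_structure(st, p, threshold, radii_table)
            row["id"] = entry_id
        except (StructureError, ValueError, OSError) as exc:
            logger.warning("survey entry %s failed: %s", entry_id, exc)
            row = {c: None for c in RECORD_COLUMNS}
            row.update({"id": entry_id, "chains": chains or "", "status": f"error: {exc}"})
        rows.append(row)
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return df


def format_tsv(df: pd.DataFrame) -> str:
    """Render a survey table with fixed column precision (deterministic bytes)."""
    out = df.copy()
    for col, dp in _FORMATS.items():
        out[col] = out[col].map(
            lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.{dp}f}"
        )
    for col in out.columns:
        out[col] = out[col].map(lambda v: "" if v is None else v)
    return out.to_csv(sep="\t", index=False, lineterminator="\n")


def summarize(df: pd.DataFrame, h_bins: int | Sequence[float] = 20) -> dict:
    """Aggregate survey statistics over records with a defined s.

    The pocket threshold is recomputed as mean(s) − 3·sd(s) (sample sd); with
    fewer than two defined s values the threshold is omitted.
    """
    ok = df[df["status"] == "ok"]
    s_vals = ok["s"].dropna().astype(float)
    summary: dict = {"n_structures": int(len(df)), "n_ok": int(len(ok))}
    if len(s_vals) >= 2:
        s_mean = float(s_vals.mean())
        s_sd = float(s_vals.std(ddof=1))
        summary.update(
            s_mean=s_mean,
            s_sd=s_sd,
            pocket_threshold=s_mean - 3.0 * s_sd,
        )
    elif len(s_vals) == 1:
        summary.update(s_mean=float(s_vals.iloc[0]), s_sd=None, pocket_threshold=None)
    labels = ok["label"].dropna()
    summary["n_pockets"] = int((labels == "pocket").sum())
    summary["n_cavities"] = int((labels == "cavity").sum())
    h_vals = ok["H"].dropna().astype(float)
    if len(h_vals):
        counts, edges = np.histogram(h_vals, bins=h_bins)
        summary["h_histogram"] = {"edges": edges.tolist(), "counts": counts.tolist()}
        top = ok.dropna(subset=["H"]).sort_values("H")
        summary["extremes"] = {
            "most_hydrophilic": top.head(3)["id"].tolist(),
            "most_hydrophobic": top.tail(3)["id"].tolist()[::-1],
            "largest_v_c": ok.dropna(subset=["v_c_nm3"])
            .sort_values("v_c_nm3", ascending=False)
            .head(3)["id"]
            .tolist(),
            "most_closed": ok.dropna(subset=["s"])
            .sort_values("s", ascending=False)
            .head(3)["id"]
            .tolist(),
        }
    return summary
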