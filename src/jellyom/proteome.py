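"""Label-free protein pool turnover via PSMs per amino-acid residue.

Each protein's abundance proxy is its peptide-spectrum-match count divided
by its residue count (PSMs/AA); pool totals are the sum over all proteins
detected at a timepoint, and consumption percentages follow from the
decline of that total. Floor filtering (relative abundance < 1%) affects
reporting only, never pool totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .stoichiometry import fraction_consumed

PSM_TSV_COLUMNS = ["protein_id", "annotation", "aa_length", "psms", "timepoint_h"]


@dataclass(frozen=True)
class PSMRecord:
    """One protein's spectral evidence at one timepoint."""

    protein_id: str
    annotation: str
    aa_length: int
    psms: float
    timepoint_h: float

    def __post_init__(self) -> None:
        if self.aa_length <= 0:
            raise ValueError("aa_length must be > 0")
        if self.psms < 0:
            raise ValueError("psms must be >= 0")


@dataclass
class ProteinPool:
    """Pool state at one timepoint: total PSMs/AA and per-protein shares."""

    timepoint_h: float
    total_psm_per_aa: float
    per_protein_rel_pct: dict[str, float]
    report: dict[str, float]  # floor-filtered, remainder under "others"


def psm_per_aa(record: PSMRecord) -> float:
    """Abundance proxy: spectral matches per residue."""
    return record.psms / record.aa_length


def pool_total(records: list[PSMRecord]) -> float:
    """Sum of PSMs/AA over all proteins detected at one timepoint."""
    seen: set[str] = set()
    total = 0.0
    for r in records:
        if r.protein_id in seen:
            raise ValueError(
                f"duplicate protein_id {r.protein_id!r} at one timepoint"
            )
        seen.add(r.protein_id)
        total += psm_per_aa(r)
    return total


def pool_consumed_pct(t0_total: float, t_total: float) -> float:
    """Percentage of the initial pool consumed between two timepoints."""
    return fraction_consumed(t0_total, t_total)


def relative_abundance_table(
    records: list[PSMRecord], report_floor_pct: float = 1.0
) -> ProteinPool:
    """Per-protein share of the timepoint total, with a reporting floor.

    Proteins below ``report_floor_pct`` are rolled into ``"others"`` in the
    filtered report; the unfiltered percentages always sum to 100.
    """
    total = pool_total(records)
    if total <= 0:
        raise ValueError("pool total is zero: relative abundances undefined")
    rel = {r.protein_id: 100.0 * psm_per_aa(r) / total for r in records}
    report: dict[str, float] = {}
    others = 0.0
    for pid, pct in sorted(rel.items(), key=lambda kv: -kv[1]):
        if pct >= report_floor_pct:
            report[pid] = pct
        else:
            others += pct
    if others > 0:
        report["others"] = others
    timepoints = {r.timepoint_h for r in records}
    t = timepoints.pop() if len(timepoints) == 1 else float("nan")
    return ProteinPool(
        timepoint_h=t, total_psm_per_aa=total, per_protein_rel_pct=rel, report=report
    )


def annotation_rollup(
    records: list[PSMRecord], category_map: dict[str, str]
) -> dict[str, float]:
    """Relative abundance by annotation category; unmapped proteins fall
    into ``"uncharacterized"``. Percentages sum to 100."""
    total = pool_total(records)
    if total <= 0:
        raise ValueError("pool total is zero")
    shares: dict[str, float] = {}
    for r in records:
        cat = category_map.get(r.protein_id, "uncharacterized")
        shares[cat] = shares.get(cat, 0.0) + 100.0 * psm_per_aa(r) / total
    return shares


def read_psm_tsv(path) -> list[PSMRecord]:
    """Load a PSM table (TSV with protein_id, annotation, aa_length, psms,
    timepoint_h)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PSM_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table missing columns: {missing}")
    return [
        PSMRecord(
            protein_id=str(row.protein_id),
            annotation=str(row.annotation),
            aa_length=int(row.aa_length),
            psms=float(row.psms),
            timepoint_h=float(row.timepoint_h),
        )
        for row in df.itertuples()
    ]


def by_timepoint(records: list[PSMRecord]) -> dict[float, list[PSMRecord]]:
    out: dict[float, list[PSMRecord]] = {}
    for r in records:
        out.setdefault(r.timepoint_h, []).append(r)
    return dict(sorted(out.items()))


def turnover_table(
    records: list[PSMRecord], report_floor_pct: float = 1.0
) -> pd.DataFrame:
    """Long-format turnover table: (timepoint, protein, PSMs/AA, rel %).

    Restricted to proteins exceeding the floor at >= 1 timepoint; all other
    proteins appear as an aggregated "others" row per timepoint.
    """
    groups = by_timepoint(records)
    pools = {t: relative_abundance_table(recs, report_floor_pct) for t, recs in groups.items()}
    keep = {
        pid
        for pool in pools.values()
        for pid, pct in pool.per_protein_rel_pct.items()
        if pct >= report_floor_pct
    }
    rows = []
    for t, recs in groups.items():
        pool = pools[t]
        others_abs = others_rel = 0.0
        for r in recs:
            abs_val = psm_per_aa(r)
            rel = pool.per_protein_rel_pct[r.protein_id]
            if r.protein_id in keep:
                rows.append(
                    {"timepoint_h": t, "protein_id": r.protein_id,
                     "psm_per_aa": abs_val, "rel_pct": rel}
                )
            else:
                others_abs += abs_val
                others_rel += rel
        if others_abs > 0:
            rows.append(
                {"timepoint_h": t, "protein_id": "others",
                 "psm_per_aa": others_abs, "rel_pct": others_rel}
            )
    return pd.DataFrame(rows)
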