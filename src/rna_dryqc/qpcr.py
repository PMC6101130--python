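"""Efficiency-corrected Cp arithmetic for RT-qPCR.

An assay with amplification efficiency E (fold amplification per cycle,
1 < E <= 2) reaches its quantification threshold after Cp cycles, i.e. the
template scales as E^-Cp.  Rescaling to base 2,

    Cp' = Cp * log2(E)

puts every assay on a common cycle scale, after which the usual base-2
arithmetic applies:

* integrity ratio (3'/5' assay): 2^-(Cp'3 - Cp'5) — equals 1 for intact RNA
  and rises when the 3' amplicon is in excess, the degradation signature
  under oligo(dT) priming;
* relative expression: 2^-(Cp'target - Cp'reference), normalized to a
  reference gene such as ACTB.

Replicate Cp values are averaged on the cycle scale (the geometric mean of
the underlying quantities) before correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class QPCRRecord:
    sample_id: str
    group: str
    pair_id: str
    target: str
    cp_values: tuple[float, ...]
    efficiency: float = 2.0
    nort_cp: float | None = None  # no-reverse-transcriptase control

    def __post_init__(self) -> None:
        if not self.cp_values:
            raise ValueError(f"{self.sample_id}/{self.target}: at least one Cp replicate required")
        if any(c <= 0 for c in self.cp_values):
            raise ValueError(f"{self.sample_id}/{self.target}: Cp values must be positive")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError(f"{self.sample_id}/{self.target}: efficiency must be in (1, 2]")

    @property
    def mean_cp(self) -> float:
        return float(np.mean(self.cp_values))

    @property
    def sd_cp(self) -> float:
        return float(np.std(self.cp_values, ddof=1)) if len(self.cp_values) > 1 else 0.0

    @property
    def nort_flag(self) -> bool:
        """True when the no-RT control is within 5 cycles of the RT Cp."""
        return self.nort_cp is not None and (self.nort_cp - self.mean_cp) < 5.0


def corrected_cp(cp, efficiency: float) -> float:
    """Efficiency-corrected Cp' = mean(Cp) * log2(E)."""
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency}")
    return float(np.mean(cp)) * math.log2(efficiency)


@dataclass(frozen=True)
class IntegrityResult:
    sample_id: str
    cp5_corrected: float
    cp3_corrected: float
    ratio: float


def integrity_ratio(record5: QPCRRecord, record3: QPCRRecord) -> IntegrityResult:
    """3'/5' integrity ratio 2^-(Cp'3 - Cp'5) for one sample."""
    if record5.sample_id != record3.sample_id:
        raise ValueError(f"5' assay is for {record5.sample_id} but 3' assay for {record3.sample_id}")
    c5 = corrected_cp(record5.cp_values, record5.efficiency)
    c3 = corrected_cp(record3.cp_values, record3.efficiency)
    return IntegrityResult(record5.sample_id, c5, c3, 2.0 ** (-(c3 - c5)))


def relative_expression(target: QPCRRecord, reference: QPCRRecord) -> float:
    """Reference-normalized expression 2^-(Cp'target - Cp'reference)."""
    if target.sample_id != reference.sample_id:
        raise ValueError(f"target is for {target.sample_id} but reference for {reference.sample_id}")
    ct = corrected_cp(target.cp_values, target.efficiency)
    cr = corrected_cp(reference.cp_values, reference.efficiency)
    return 2.0 ** (-(ct - cr))


def paired_group_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided paired t-test; returns (mean difference, P).

    Pairs with a missing member must be dropped by the caller.  Degenerate
    zero-variance differences follow the documented convention: P = 1 when
    the common difference is 0, else P = 0 (infinitely significant).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired test needs equal-length vectors")
    if a.size < 2:
        raise ValueError("need >=2 complete pairs")
    diff = a - b
    mean_diff = float(diff.mean())
    if np.allclose(diff, diff[0]):
        return mean_diff, 1.0 if math.isclose(mean_diff, 0.0, abs_tol=1e-12) else 0.0
    res = stats.ttest_rel(a, b)
    return mean_diff, float(res.pvalue)


# ---------------------------------------------------------------------------
# Table-level drivers
# ---------------------------------------------------------------------------


def read_cp_table(path) -> list[QPCRRecord]:
    """Read a Cp table (CSV/TSV with columns sample, group, pair_id, target,
    cp_rep1..n, efficiency, optional nort_cp)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    rep_cols = sorted(c for c in df.columns if c.startswith("cp_rep"))
    if not rep_cols:
        raise ValueError(f"{path}: no cp_rep* columns found")
    records = []
    for _, row in df.iterrows():
        cps = tuple(float(row[c]) for c in rep_cols if pd.notna(row[c]))
        nort = float(row["nort_cp"]) if "nort_cp" in df.columns and pd.notna(row.get("nort_cp")) else None
        records.append(
            QPCRRecord(
                sample_id=str(row["sample"]),
                group=str(row["group"]),
                pair_id=str(row["pair_id"]),
                target=str(row["target"]),
                cp_values=cps,
                efficiency=float(row.get("efficiency", 2.0)),
                nort_cp=nort,
            )
        )
    return records


def _by_sample_target(records) -> dict[tuple[str, str], QPCRRecord]:
    return {(r.sample_id, r.target): r for r in records}


def integrity_table(records, assay5: str, assay3: str) -> pd.DataFrame:
    """Per-sample integrity ratios for a 5'/3' assay pair."""
    idx = _by_sample_target(records)
    samples = sorted({r.sample_id for r in records})
    rows = []
    for s in samples:
        r5, r3 = idx.get((s, assay5)), idx.get((s, assay3))
        if r5 is None or r3 is None:
            raise ValueError(f"sample {s}: missing {assay5 if r5 is None else assay3} assay")
        res = integrity_ratio(r5, r3)
        rows.append((s, r5.group, r5.pair_id, res.cp5_corrected, res.cp3_corrected, res.ratio,
                     r5.nort_flag or r3.nort_flag))
    return pd.DataFrame(
        rows, columns=["sample", "group", "pair_id", "cp5_corrected", "cp3_corrected", "ratio", "nort_flag"]
    ).set_index("sample")


def expression_table(records, reference: str) -> pd.DataFrame:
    """Per-sample, per-target expression normalized to ``reference``."""
    idx = _by_sample_target(records)
    rows = []
    for r in records:
        if r.target == reference:
            continue
        ref = idx.get((r.sample_id, reference))
        if ref is None:
            raise ValueError(f"sample {r.sample_id}: missing reference assay {reference}")
        rows.append((r.sample_id, r.group, r.pair_id, r.target,
                     relative_expression(r, ref), r.nort_flag))
    return pd.DataFrame(rows, columns=["sample", "group", "pair_id", "target", "expression", "nort_flag"])


def paired_tests_by_target(expr: pd.DataFrame, control: str, treated: str) -> pd.DataFrame:
    """Paired t-test per target between the two groups, matched on pair_id."""
    rows = []
    for target, sub in expr.groupby("target"):
        piv = sub.pivot_table(index="pair_id", columns="group", values="expression")
        piv = piv.dropna(subset=[control, treated])
        if len(piv) < 2:
            rows.append((target, len(piv), np.nan, np.nan))
            continue
        md, p = paired_group_test(piv[control], piv[treated])
        rows.append((target, len(piv), md, p))
    return pd.DataFrame(rows, columns=["target", "n_pairs", "mean_difference", "p_value"]).set_index("target")
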