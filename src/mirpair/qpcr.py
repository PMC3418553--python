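"""-ddCT relative quantification and paired tumor/normal qPCR validation.

Relative expression of an assay in a sample is ``-ddCT = -(dCT -
dCT_calibrator)`` where ``dCT = CT - CT_reference`` normalizes against an
endogenous control (U6 for miRNAs, beta-actin for mRNAs) and the
calibrator is the sample whose dCT sits closest to the cohort median.
Assays whose CT exceeds ``ct_max`` (default 35 cycles) or is undefined in
more than half the samples are excluded as non-amplifying.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anticorr import pearson
from .matrix import MatrixError

__all__ = [
    "AssayQc",
    "PlateResult",
    "read_ct_table",
    "choose_calibrator",
    "compute_neg_ddct",
    "analyze_plate",
    "paired_group_test",
    "validate_pairs",
]

CT_COLUMNS = ["sample_id", "patient_id", "group", "assay_id", "ct", "ref_ct"]


@dataclass(frozen=True)
class AssayQc:
    assay_id: str
    n_total: int
    n_failed: int
    excluded: bool


@dataclass
class PlateResult:
    """Per-sample measurements and per-assay QC for one CT table."""

    measurements: pd.DataFrame   # CT_COLUMNS + delta_ct, neg_ddct
    qc: dict                     # assay_id -> AssayQc

    def assay(self, assay_id: str) -> pd.DataFrame:
        return self.measurements[self.measurements["assay_id"] == assay_id]


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str})
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks columns {sorted(missing)}")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    df["ref_ct"] = pd.to_numeric(df["ref_ct"], errors="coerce")
    return df


def choose_calibrator(delta_cts: pd.Series) -> str:
    """Sample whose dCT is closest to the median; ties -> lexicographic."""
    vals = delta_cts.dropna()
    if vals.empty:
        raise ValueError("no sample with a defined delta CT")
    med = float(np.median(vals.to_numpy()))
    dist = (vals - med).abs()
    best = dist[dist == dist.min()].index
    return sorted(best)[0]


def compute_neg_ddct(
    table: pd.DataFrame,
    assay_id: str,
    ct_max: float = 35.0,
    fail_fraction: float = 0.5,
):
    """Per-sample dCT and -ddCT for one assay, plus its QC record.

    Samples whose CT is missing or above ``ct_max`` are excluded from the
    statistics and counted as failures; the assay is flagged excluded when
    the failure fraction exceeds ``fail_fraction``. Samples lacking the
    reference CT are dropped with a warning (not counted as assay failure).
    """
    sub = table[table["assay_id"] == assay_id].copy()
    if sub.empty:
        raise ValueError(f"assay {assay_id!r} absent from table")
    no_ref = sub["ref_ct"].isna()
    if no_ref.any():
        warnings.warn(f"{assay_id}: dropping {int(no_ref.sum())} samples without reference CT")
        sub = sub[~no_ref]
    failed = sub["ct"].isna() | (sub["ct"] > ct_max)
    n_total = int(len(sub))
    n_failed = int(failed.sum())
    qc = AssayQc(
        assay_id=assay_id,
        n_total=n_total,
        n_failed=n_failed,
        excluded=bool(n_total == 0 or n_failed / n_total > fail_fraction),
    )
    sub = sub[~failed].copy()
    sub["delta_ct"] = sub["ct"] - sub["ref_ct"]
    if len(sub):
        cal = choose_calibrator(sub.set_index("sample_id")["delta_ct"])
        cal_dct = float(sub.loc[sub["sample_id"] == cal, "delta_ct"].iloc[0])
        sub["neg_ddct"] = -(sub["delta_ct"] - cal_dct)
    else:
        sub["neg_ddct"] = pd.Series(dtype=float)
    return sub.reset_index(drop=True), qc


def analyze_plate(table: pd.DataFrame, ct_max: float = 35.0, fail_fraction: float = 0.5) -> PlateResult:
    frames, qcs = [], {}
    for assay in pd.unique(table["assay_id"]):
        meas, qc = compute_neg_ddct(table, assay, ct_max=ct_max, fail_fraction=fail_fraction)
        qcs[assay] = qc
        if not qc.excluded:
            frames.append(meas)
    measurements = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=CT_COLUMNS + ["delta_ct", "neg_ddct"])
    )
    return PlateResult(measurements=measurements, qc=qcs)


def paired_group_test(measurements: pd.DataFrame):
    """Paired t on per-patient tumor - normal -ddCT.

    Patients lacking either group are dropped with a warning; fewer than
    two complete patients is an error.
    """
    from scipy import stats

    piv = measurements.pivot_table(index="patient_id", columns="group", values="neg_ddct", aggfunc="mean")
    complete = piv.dropna(subset=["tumor", "normal"]) if {"tumor", "normal"} <= set(piv.columns) else piv.iloc[0:0]
    n_dropped = len(piv) - len(complete)
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} patients without a complete tumor/normal pair")
    if len(complete) < 2:
        raise MatrixError("paired test needs >= 2 complete patients")
    d = (complete["tumor"] - complete["normal"]).to_numpy()
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        raise MatrixError("zero difference SD in paired qPCR test")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def validate_pairs(plate_mirna: PlateResult, plate_mrna: PlateResult, pairs) -> pd.DataFrame:
    """Pearson r/p between -ddCT vectors of each (miRNA, mRNA) assay pair.

    A pair is ``evaluable`` only when both assays survived QC and share
    at least 3 samples; significance = r < 0 and p < 0.05.
    """
    rows = []
    for mi, mr in pairs:
        row = {"mirna_id": mi, "mrna_id": mr, "n": 0, "r": np.nan,
               "p_value": np.nan, "evaluable": False, "significant": False}
        qc_mi = plate_mirna.qc.get(mi)
        qc_mr = plate_mrna.qc.get(mr)
        if qc_mi is None or qc_mr is None:
            row["reason"] = "assay missing"
        elif qc_mi.excluded or qc_mr.excluded:
            row["reason"] = "assay excluded by QC"
        else:
            # plates index samples independently; match on patient+group
            am = plate_mirna.assay(mi).set_index(["patient_id", "group"])["neg_ddct"]
            bm = plate_mrna.assay(mr).set_index(["patient_id", "group"])["neg_ddct"]
            shared = am.index.intersection(bm.index)
            if len(shared) < 3:
                raise MatrixError(
                    f"pair ({mi}, {mr}): fewer than 3 shared samples"
                )
            r, p = pearson(am.loc[shared].to_numpy(), bm.loc[shared].to_numpy())
            row.update(n=len(shared), r=r, p_value=p, evaluable=True,
                       significant=bool(r < 0 and p < 0.05), reason="")
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["mirna_id", "mrna_id", "n", "r", "p_value", "evaluable", "significant", "reason"]
    )
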