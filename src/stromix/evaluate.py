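"""Scoring of decoded CNV calls against a known truth.

Recovery rate is the proportion of SNPs whose detected value (copy number
or allelic imbalance) exactly equals the truth. For comparison with
callers that model only six states, the full state space collapses to
{0n, 1n, FF, FM, 3n, >=4n}: copy number 2 splits by allelic imbalance into
copy-neutral LOH ('FF') and normal ('FM'). The false discovery rate of a
class is the fraction of SNPs detected as that class whose truth differs.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .states import CNVState

__all__ = ["recovery_rate", "collapse_state", "collapse_states", "fdr",
           "evaluation_report", "SIX_STATE_LABELS"]

SIX_STATE_LABELS = ("0n", "1n", "FF", "FM", "3n", ">=4n")

#: sentinel returned by fdr() when no SNP was detected as the class
FDR_UNDEFINED = float("nan")


def recovery_rate(truth: Sequence, detected: Sequence) -> float:
    """Exact-match proportion between per-SNP truth and detection."""
    truth = np.asarray(truth)
    detected = np.asarray(detected)
    if truth.shape != detected.shape:
        raise ValueError(
            f"length mismatch: truth {truth.shape} vs detected {detected.shape}")
    if truth.size == 0:
        raise ValueError("empty inputs")
    return float(np.mean(truth == detected))


def collapse_state(name: str) -> str:
    """Map a full state name to the coarse six-state label."""
    st = CNVState(name)
    cn = st.copy_number
    if cn == 0:
        return "0n"
    if cn == 1:
        return "1n"
    if cn == 2:
        return "FF" if st.is_loh else "FM"
    if cn == 3:
        return "3n"
    return ">=4n"


def collapse_states(names: Sequence[str]) -> np.ndarray:
    return np.array([collapse_state(n) for n in names])


def fdr(truth_labels: Sequence, detected_labels: Sequence, cls) -> float:
    """Among SNPs detected as ``cls``, the fraction whose truth differs.

    NaN when nothing was detected as the class (0/0).
    """
    truth = np.asarray(truth_labels)
    detected = np.asarray(detected_labels)
    if truth.shape != detected.shape:
        raise ValueError("length mismatch between truth and detected labels")
    sel = detected == cls
    n = int(sel.sum())
    if n == 0:
        return FDR_UNDEFINED
    return float(np.sum(truth[sel] != cls) / n)


def evaluation_report(truth: pd.DataFrame, detected: pd.DataFrame) -> pd.DataFrame:
    """Per-class scoring table from per-SNP truth and detection frames.

    Both frames need columns state/cn/ai, aligned SNP-for-SNP. Rows are the
    six collapsed classes (only those present in truth or detection) plus an
    'overall' row; columns: n_snps_true, n_snps_detected, recovery_cn,
    recovery_ai, fdr.
    """
    if len(truth) != len(detected):
        raise ValueError("truth and detected tables differ in length")
    t_cls = collapse_states(truth["state"])
    d_cls = collapse_states(detected["state"])
    t_cn = np.asarray(truth["cn"])
    d_cn = np.asarray(detected["cn"])
    t_ai = np.asarray(truth["ai"], dtype=float)
    d_ai = np.asarray(detected["ai"], dtype=float)
    rows = []
    for cls in SIX_STATE_LABELS:
        in_t = t_cls == cls
        if not in_t.any() and not (d_cls == cls).any():
            continue
        rows.append({
            "class": cls,
            "n_snps_true": int(in_t.sum()),
            "n_snps_detected": int((d_cls == cls).sum()),
            "recovery_cn": (float(np.mean(d_cn[in_t] == t_cn[in_t]))
                            if in_t.any() else math.nan),
            "recovery_ai": (float(np.mean(d_ai[in_t] == t_ai[in_t]))
                            if in_t.any() else math.nan),
            "fdr": fdr(t_cls, d_cls, cls),
        })
    rows.append({
        "class": "overall",
        "n_snps_true": len(truth),
        "n_snps_detected": len(detected),
        "recovery_cn": recovery_rate(t_cn, d_cn),
        "recovery_ai": recovery_rate(t_ai, d_ai),
        "fdr": float(np.mean(t_cls != d_cls)),
    })
    return pd.DataFrame(rows)
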