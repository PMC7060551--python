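"""The metATAC chromatin-accessibility signature and patient scoring.

A signature is the set of peaks robustly differential between metastatic and
parental cell populations (default adjusted p < 5e-5).  Each cohort sample is
scored by correlating its normalized accessibility over the signature peaks
with the mean parental profile (``r_par``) and the mean metastatic profile
(``r_met``):

    S = r_met - r_par + 1

The +1 keeps scores positive; S ranges over [-1, 3] by the bounds of the
Pearson coefficient, and S > 1 indicates a chromatin landscape closer to the
metastatic populations.  Organotropic variants (lung- or brain-specific
scores) use the same code path with the metastatic replicate list restricted
to one sub-population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SignalSet",
    "MetatacScore",
    "select_signature_peaks",
    "build_signal_sets",
    "score_patient",
    "score_cohort",
    "scores_to_frame",
    "stratify_median",
]


@dataclass
class SignalSet:
    """Mean parental and metastatic signal over the signature peaks."""

    peak_ids: list[str]
    par_signal: np.ndarray
    met_signal: np.ndarray

    def __post_init__(self) -> None:
        self.par_signal = np.asarray(self.par_signal, dtype=float)
        self.met_signal = np.asarray(self.met_signal, dtype=float)
        n = len(self.peak_ids)
        if n < 3:
            raise ValueError("signature needs >= 3 peaks")
        if len(self.par_signal) != n or len(self.met_signal) != n:
            raise ValueError("signal vectors must match peak_ids length")

    @classmethod
    def from_tsv(cls, path) -> "SignalSet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df["par_signal"].to_numpy(), df["met_signal"].to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"par_signal": self.par_signal, "met_signal": self.met_signal},
            index=pd.Index(self.peak_ids, name="peak_id"),
        ).to_csv(path, sep="\t", float_format="%.6g")


@dataclass(frozen=True)
class MetatacScore:
    """Per-patient correlation pair and score ``s = r_met - r_par + 1``."""

    patient_id: str
    r_par: float
    r_met: float

    @property
    def s(self) -> float:
        return self.r_met - self.r_par + 1.0


def select_signature_peaks(
    diff: pd.DataFrame, alpha: float = 5e-5
) -> list[str]:
    """Peak ids with ``padj < alpha`` from a differential result, order kept.

    Fewer than 3 survivors is an error: the correlation score is undefined or
    unstable on shorter vectors.
    """
    ids = list(diff.index[diff["padj"] < alpha])
    if len(ids) < 3:
        raise ValueError(
            f"only {len(ids)} peaks pass padj < {alpha}; "
            "signature requires >= 3"
        )
    return ids


def build_signal_sets(
    norm: pd.DataFrame,
    parental_ids: Sequence[str],
    metastatic_ids: Sequence[str],
    signature_peaks: Sequence[str],
) -> SignalSet:
    """Average normalized signal over replicates, restricted to the signature.

    ``norm`` is the normalized (log-CPM, quantile-normalized) matrix over the
    shared peak universe, peaks x samples.
    """
    for col in list(parental_ids) + list(metastatic_ids):
        if col not in norm.columns:
            raise KeyError(f"replicate column {col!r} missing from matrix")
    missing = [p for p in signature_peaks if p not in norm.index]
    if missing:
        raise KeyError(f"signature peaks missing from matrix: {missing[:5]}")
    sub = norm.loc[list(signature_peaks)]
    return SignalSet(
        list(signature_peaks),
        sub[list(parental_ids)].mean(axis=1).to_numpy(),
        sub[list(metastatic_ids)].mean(axis=1).to_numpy(),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def score_patient(
    patient_signal: Sequence[float],
    sig: SignalSet,
    patient_id: str = "patient",
) -> MetatacScore:
    """Score one patient vector aligned to ``sig.peak_ids``."""
    x = np.asarray(patient_signal, dtype=float)
    if len(x) != len(sig.peak_ids):
        raise ValueError("patient vector not aligned to signature peaks")
    return MetatacScore(
        patient_id, _pearson(x, sig.par_signal), _pearson(x, sig.met_signal)
    )


def score_cohort(
    cohort_signal: pd.DataFrame, sig: SignalSet
) -> tuple[list[MetatacScore], dict[str, str]]:
    """Score every patient (rows) of a cohort matrix.

    Columns must cover the signature peaks (strict alignment, no imputation).
    Per-patient failures (e.g. constant signal) are collected in the returned
    error mapping while the rest of the cohort is scored.
    """
    missing = [p for p in sig.peak_ids if p not in cohort_signal.columns]
    if missing:
        raise KeyError(f"cohort matrix lacks signature peaks: {missing[:5]}")
    aligned = cohort_signal[sig.peak_ids]
    scores: list[MetatacScore] = []
    errors: dict[str, str] = {}
    for pid, row in aligned.iterrows():
        try:
            scores.append(score_patient(row.to_numpy(), sig, str(pid)))
        except ValueError as exc:
            errors[str(pid)] = str(exc)
    return scores, errors


def scores_to_frame(scores: Sequence[MetatacScore]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "r_par": [m.r_par for m in scores],
            "r_met": [m.r_met for m in scores],
            "s": [m.s for m in scores],
        },
        index=pd.Index([m.patient_id for m in scores], name="patient_id"),
    )
    return df


def stratify_median(scores: Sequence[float]) -> list[str]:
    """Median split into ``high`` (> median) and ``low`` (<= median).

    Scores exactly at the median go to the low stratum; all-identical scores
    are an error (no informative split exists).
    """
    x = np.asarray(scores, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 scores to stratify")
    med = float(np.median(x))
    if np.all(x == x[0]):
        raise ValueError("all scores identical; median split undefined")
    return ["high" if v > med else "low" for v in x]
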