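"""Prior-shift adjustment of the prediction-probability cutoff.

A predictor trained on cell lines is calibrated to the source responder
prevalence.  When the responder odds differ between domains by the odds
ratio

    r = (P_S(Y=1)/P_S(Y=0)) / (P_T(Y=1)/P_T(Y=0)),

source-trained probabilities on target samples are over-estimated for
r > 1 and under-estimated for r < 1, and the decision cutoff should move
from 0.5 to r/(r+1) (equal to 0.5 iff r = 1).  The adjustment applies to
continuous probability outputs (LogitDA); it does not apply to
majority-vote KNN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets_io import DataError, ResponseLabels


@dataclass
class CutoffAdjustment:
    ns_source: int
    nr_source: int
    ns_target: int
    nr_target: int
    r: float
    cutoff: float

    @classmethod
    def from_labels(
        cls, source_labels: ResponseLabels, target_labels: ResponseLabels
    ) -> "CutoffAdjustment":
        r = odds_ratio(source_labels, target_labels)
        return cls(
            ns_source=source_labels.n_sensitive,
            nr_source=source_labels.n_resistant,
            ns_target=target_labels.n_sensitive,
            nr_target=target_labels.n_resistant,
            r=r,
            cutoff=adjusted_cutoff(r),
        )

    @classmethod
    def from_counts(
        cls, ns_source: int, nr_source: int, ns_target: int, nr_target: int
    ) -> "CutoffAdjustment":
        r = odds_ratio_from_counts(ns_source, nr_source, ns_target, nr_target)
        return cls(ns_source, nr_source, ns_target, nr_target, r, adjusted_cutoff(r))

    def to_dict(self) -> dict:
        return {
            "ns_source": self.ns_source,
            "nr_source": self.nr_source,
            "ns_target": self.ns_target,
            "nr_target": self.nr_target,
            "r": self.r,
            "cutoff": self.cutoff,
            "cutoff_2dp": round(self.cutoff, 2),
        }


def odds_ratio_from_counts(
    ns_source: int, nr_source: int, ns_target: int, nr_target: int
) -> float:
    """Source-to-target responder odds ratio from empirical class counts."""
    counts = {
        "source sensitive": ns_source,
        "source resistant": nr_source,
        "target sensitive": ns_target,
        "target resistant": nr_target,
    }
    zero = [k for k, v in counts.items() if v <= 0]
    if zero:
        raise DataError(
            f"odds ratio needs all four class counts positive (the adjustment's "
            f"precondition); zero/negative: {zero}"
        )
    return (ns_source / nr_source) / (ns_target / nr_target)


def odds_ratio(source_labels: ResponseLabels, target_labels: ResponseLabels) -> float:
    return odds_ratio_from_counts(
        source_labels.n_sensitive,
        source_labels.n_resistant,
        target_labels.n_sensitive,
        target_labels.n_resistant,
    )


def adjusted_cutoff(r: float) -> float:
    """The prior-shift-corrected decision cutoff r/(1+r), in (0,1)."""
    if not np.isfinite(r) or r <= 0:
        raise DataError(f"odds ratio must be a positive finite number, got {r}")
    return float(r / (1.0 + r))


def classify_with_cutoff(scores: np.ndarray, cutoff: float) -> np.ndarray:
    """Label 1 iff score > cutoff (strict; a score equal to the cutoff is 0)."""
    scores = np.asarray(scores, dtype=float)
    if not 0.0 < cutoff < 1.0:
        raise DataError(f"cutoff must lie in (0,1), got {cutoff}")
    if ((scores < 0) | (scores > 1)).any():
        raise DataError("scores must lie in [0,1]")
    return (scores > cutoff).astype(int)
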