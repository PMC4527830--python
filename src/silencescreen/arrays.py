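"""Two-channel barcode-array layer: hybridization, normalization, hit calling.

Genomic DNA from the paired cultures is amplified and labelled — the +5-FOA
culture with Cy3 and the −5-FOA culture with Cy5 — and cohybridized to an
array of the strain TAGs.  A strain enriched by counter-selection (a
long-lived candidate) therefore has a *small* Cy5:Cy3 ratio: its Cy3
(denominator, +5-FOA) signal rises while Cy5 tracks the neutral culture, so
long-lived candidates sit at negative log2 Cy5:Cy3, matching the published
sign convention.

The classification rule: a strain is called potentially long-lived when its
normalized log2 Cy5:Cy3 ratio is negative at both day 6 and day 16 and falls
below −2.3 at day 16 (strict inequalities).  A parallel control library with
the reporter at a constitutively silent locus catches strains whose reporter
expression is stochastically defective rather than age-dependent: any strain
whose control-library day-16 ratio deviates from zero by more than a
tolerance is flagged and declassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen import AbundanceTrajectory
from .strains import Library

__all__ = [
    "ArraySample",
    "ScreenCall",
    "RecoveryReport",
    "simulate_hybridization",
    "normalize_log_ratios",
    "classify_long_lived",
    "control_filter",
    "recovery_report",
]

logger = logging.getLogger(__name__)

#: intensities below this fraction of the per-channel median are floored so
#: that extinct strains yield finite (floor-limited) ratios
DETECTION_FLOOR_FRAC = 1e-6


@dataclass(frozen=True)
class ArraySample:
    """Per-barcode two-channel intensities and log2 Cy5:Cy3 ratios at one day."""

    day: int
    data: pd.DataFrame  # columns: barcode_id, cy5, cy3, log2_ratio
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.data[["cy5", "cy3"]] <= 0).any().any():
            raise ValueError("intensities must be positive (after flooring)")

    @property
    def barcode_ids(self) -> list[str]:
        return self.data["barcode_id"].tolist()

    def ratios(self) -> pd.Series:
        return self.data.set_index("barcode_id")["log2_ratio"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "day", self.day)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, normalized: bool = False) -> list["ArraySample"]:
        df = pd.read_csv(path, sep="\t")
        return [
            cls(day=int(day), data=sub.drop(columns="day").reset_index(drop=True),
                normalized=normalized)
            for day, sub in df.groupby("day")
        ]


@dataclass(frozen=True)
class ScreenCall:
    """Classification outcome for one barcode."""

    barcode_id: str
    ratio_day6: float
    ratio_day16: float
    classified_long_lived: bool
    control_flagged: bool = False


def _intensities(
    abundance: pd.Series, scale: float, noise_sd_log2: float, rng: np.random.Generator
) -> np.ndarray:
    eps = rng.normal(0.0, noise_sd_log2 * np.log(2.0), size=len(abundance))
    raw = scale * abundance.to_numpy() * np.exp(eps)
    floor = DETECTION_FLOOR_FRAC * np.median(raw[raw > 0]) if (raw > 0).any() else 1.0
    return np.maximum(raw, floor)


def simulate_hybridization(
    traj_plus: AbundanceTrajectory,
    traj_minus: AbundanceTrajectory,
    noise_sd_log2: float,
    seed: Optional[int] = None,
    scale: float = 1e4,
) -> list[ArraySample]:
    """Turn paired ±5-FOA abundances into noisy two-channel intensities.

    Each channel's intensity is ``scale * abundance * exp(eps)`` with
    ``eps ~ Normal(0, (noise_sd_log2 * ln 2)^2)`` drawn independently per
    channel and barcode, so with equal abundances the log2 ratios have
    standard deviation ``noise_sd_log2 * sqrt(2)``.  Cy5 is the −5-FOA
    channel, Cy3 the +5-FOA channel.
    """
    if noise_sd_log2 < 0:
        raise ValueError("noise_sd_log2 must be nonnegative")
    days = sorted(set(traj_plus.days) & set(traj_minus.days))
    if not days:
        raise ValueError("trajectories share no sampling days")
    rng = np.random.default_rng(seed)
    samples = []
    for day in days:
        ab_plus = traj_plus.fractions(day)
        ab_minus = traj_minus.fractions(day)
        if set(ab_plus.index) != set(ab_minus.index):
            raise ValueError("trajectories carry different barcode sets")
        ab_minus = ab_minus.reindex(ab_plus.index)
        cy3 = _intensities(ab_plus, scale, noise_sd_log2, rng)   # +5-FOA
        cy5 = _intensities(ab_minus, scale, noise_sd_log2, rng)  # -5-FOA
        samples.append(
            ArraySample(
                day=day,
                data=pd.DataFrame(
                    {
                        "barcode_id": ab_plus.index,
                        "cy5": cy5,
                        "cy3": cy3,
                        "log2_ratio": np.log2(cy5 / cy3),
                    }
                ),
            )
        )
    return samples


def normalize_log_ratios(sample: ArraySample) -> ArraySample:
    """Median-center the log2 ratios across barcodes (median ratio -> 0).

    Rank order is preserved; applying the normalization twice is a no-op.
    """
    if len(sample.data) < 2:
        raise ValueError("normalization needs at least 2 barcodes")
    data = sample.data.copy()
    data["log2_ratio"] = data["log2_ratio"] - data["log2_ratio"].median()
    return replace(sample, data=data, normalized=True)


def classify_long_lived(
    day6: ArraySample,
    day16: ArraySample,
    threshold: float = -2.3,
    allow_nonnegative_threshold: bool = False,
) -> list[ScreenCall]:
    """Apply the published hit rule to the day-6 and day-16 samples.

    A barcode is classified potentially long-lived iff its normalized log2
    Cy5:Cy3 ratio is < 0 on both days and < ``threshold`` at day 16 (strict).
    Samples are median-normalized first if they were not already.
    """
    if threshold >= 0 and not allow_nonnegative_threshold:
        raise ValueError(
            "a nonnegative threshold classifies un-depleted strains; "
            "pass allow_nonnegative_threshold=True to override"
        )
    if set(day6.barcode_ids) != set(day16.barcode_ids):
        raise ValueError("day-6 and day-16 samples carry different barcode sets")
    r6 = normalize_log_ratios(day6).ratios() if not day6.normalized else day6.ratios()
    r16 = normalize_log_ratios(day16).ratios() if not day16.normalized else day16.ratios()
    calls = []
    for bc in day6.barcode_ids:
        a, b = float(r6[bc]), float(r16[bc])
        calls.append(
            ScreenCall(
                barcode_id=bc,
                ratio_day6=a,
                ratio_day16=b,
                classified_long_lived=(a < 0) and (b < 0) and (b < threshold),
            )
        )
    return calls


def control_filter(
    query_calls: Sequence[ScreenCall],
    control_day16: ArraySample,
    control_tolerance: float = 1.0,
) -> list[ScreenCall]:
    """Flag strains that misbehave in the control library and declassify them.

    A strain is flagged when the magnitude of its control-library day-16
    normalized log2 ratio exceeds the tolerance — evidence of age-independent
    (stochastic) reporter misexpression.  Flagged strains cannot remain
    classified; barcodes absent from the control sample are flagged by
    convention and logged.
    """
    if control_tolerance < 0:
        raise ValueError("control_tolerance must be nonnegative")
    sample = control_day16 if control_day16.normalized else normalize_log_ratios(control_day16)
    ctrl = sample.ratios()
    out = []
    for call in query_calls:
        if call.barcode_id not in ctrl.index:
            logger.warning(
                "barcode %s missing from control sample; flagged by convention",
                call.barcode_id,
            )
            flagged = True
        else:
            flagged = abs(float(ctrl[call.barcode_id])) > control_tolerance
        out.append(
            replace(
                call,
                control_flagged=flagged,
                classified_long_lived=call.classified_long_lived and not flagged,
            )
        )
    return out


def calls_to_frame(calls: Sequence[ScreenCall], library: Optional[Library] = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "barcode_id": [c.barcode_id for c in calls],
            "ratio_day6": [c.ratio_day6 for c in calls],
            "ratio_day16": [c.ratio_day16 for c in calls],
            "classified": [int(c.classified_long_lived) for c in calls],
            "control_flagged": [int(c.control_flagged) for c in calls],
        }
    )
    if library is not None:
        df["label"] = df["barcode_id"].map(library.labels)
    return df


@dataclass(frozen=True)
class RecoveryReport:
    """Sensitivity/specificity of the hit list against planted truth."""

    n_strains: int
    n_positive_truth: int
    n_classified: int
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    precision: float
    enrichment_p: float  # hypergeometric tail P(overlap >= observed)

    def confusion(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"classified": [self.tp, self.fp], "not_classified": [self.fn, self.tn]},
            index=["planted_long_lived", "other"],
        )


def recovery_report(calls: Sequence[ScreenCall], library: Library) -> RecoveryReport:
    """Score the hit list against the library's planted labels.

    The positive truth is the ``long_lived`` label.  Enrichment of the hit
    set for planted long-lived strains is scored with the hypergeometric
    upper tail (probability of at least the observed overlap when hits are
    drawn at random without replacement).
    """
    labels = library.labels
    truth = {bc for bc, lab in labels.items() if lab == "long_lived"}
    hits = {c.barcode_id for c in calls if c.classified_long_lived}
    n = len(library)
    tp = len(hits & truth)
    fp = len(hits - truth)
    fn = len(truth - hits)
    tn = n - tp - fp - fn
    sens = tp / len(truth) if truth else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    prec = tp / len(hits) if hits else float("nan")
    if hits:
        p = float(stats.hypergeom.sf(tp - 1, n, len(truth), len(hits)))
    else:
        p = 1.0
    return RecoveryReport(
        n_strains=n,
        n_positive_truth=len(truth),
        n_classified=len(hits),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        enrichment_p=p,
    )
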