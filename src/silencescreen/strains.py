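"""Domain types and seeded generators for barcoded deletion strains.

A pooled replicative-aging screen works on a library of barcoded deletion
strains.  Each strain is summarised phenomenologically: a mean replicative
lifespan ``L`` (number of daughters a mother produces before senescence),
a dispersion (coefficient of variation) for per-mother lifespans, and the
timing of age-dependent loss of transcriptional silencing at the reporter
locus, modelled as uniform over the last 30% of each mother's own lifespan
(fraction window [0.70, 1.00] of ``L`` by default).  Strains carrying a
*stochastic* silencing defect instead lose silencing at any division with a
constant per-division probability; these are the false positives a
constitutively-silent control locus is designed to catch.

This module also generates the validation datasets used downstream:
micromanipulation dissection sets (per-mother daughter counts) and worm
reproductive-span records with sterile and matricide outcomes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StrainSpec",
    "Library",
    "DissectionSet",
    "ReproRecord",
    "ReproSet",
    "make_library",
    "sample_mother_lifespan",
    "sample_loss_generation",
    "make_dissection_set",
    "make_repro_set",
    "default_matricide_hazard",
]

LABELS = ("wildtype_like", "long_lived", "short_lived", "silencing_defective")
OUTCOMES = ("ceased", "matricide", "alive_at_end")

#: per-mother lifespan coefficient of variation used when none is given;
#: typical of published replicative-lifespan curves.
DEFAULT_LIFESPAN_CV = 0.35


def _ceil_tol(x: float) -> int:
    """Ceil with a guard against float round-up of mathematically integral values."""
    return int(math.ceil(x - 1e-9))


def _floor_tol(x: float) -> int:
    return int(math.floor(x + 1e-9))


@dataclass(frozen=True)
class StrainSpec:
    """One barcoded deletion strain.

    Parameters
    ----------
    barcode_id :
        Unique TAG identifier within a library.
    mean_lifespan :
        Mean replicative lifespan ``L`` in generations (daughters per mother).
    lifespan_cv :
        Coefficient of variation of the per-mother lifespan distribution.
    loss_frac_lo, loss_frac_hi :
        Silencing-loss window as fractions of each mother's lifespan; loss
        occurs uniformly over divisions ``ceil(lo*T) .. floor(hi*T)``.
    silencing_defect :
        If set, silencing is lost at any division with constant per-division
        probability ``defect_loss_p`` (age-independent false-positive mode).
    label :
        Planted ground truth used by recovery statistics.
    """

    barcode_id: str
    mean_lifespan: float
    lifespan_cv: float = DEFAULT_LIFESPAN_CV
    loss_frac_lo: float = 0.70
    loss_frac_hi: float = 1.00
    silencing_defect: bool = False
    defect_loss_p: float = 0.2
    label: str = "wildtype_like"

    def __post_init__(self) -> None:
        if not self.barcode_id:
            raise ValueError("barcode_id must be a nonempty string")
        if not (np.isfinite(self.mean_lifespan) and self.mean_lifespan > 0):
            raise ValueError(f"mean_lifespan must be positive, got {self.mean_lifespan}")
        if not (np.isfinite(self.lifespan_cv) and self.lifespan_cv >= 0):
            raise ValueError(f"lifespan_cv must be nonnegative, got {self.lifespan_cv}")
        for name in ("loss_frac_lo", "loss_frac_hi"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.loss_frac_lo > self.loss_frac_hi:
            raise ValueError("loss_frac_lo must not exceed loss_frac_hi")
        if not (0 < self.defect_loss_p <= 1):
            raise ValueError("defect_loss_p must lie in (0, 1]")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class Library:
    """An ordered, barcode-unique collection of strains plus the seed that built it."""

    strains: tuple[StrainSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.strains) == 0:
            raise ValueError("library must be nonempty")
        ids = [s.barcode_id for s in self.strains]
        if len(set(ids)) != len(ids):
            raise ValueError("barcode ids must be distinct within a library")

    def __len__(self) -> int:
        return len(self.strains)

    @property
    def barcode_ids(self) -> list[str]:
        return [s.barcode_id for s in self.strains]

    @property
    def labels(self) -> dict[str, str]:
        return {s.barcode_id: s.label for s in self.strains}

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "barcode_id": [s.barcode_id for s in self.strains],
                "mean_lifespan": [s.mean_lifespan for s in self.strains],
                "lifespan_cv": [s.lifespan_cv for s in self.strains],
                "loss_frac_lo": [s.loss_frac_lo for s in self.strains],
                "loss_frac_hi": [s.loss_frac_hi for s in self.strains],
                "silencing_defect": [int(s.silencing_defect) for s in self.strains],
                "label": [s.label for s in self.strains],
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, seed: int = 0) -> "Library":
        df = pd.read_csv(path, sep="\t")
        strains = tuple(
            StrainSpec(
                barcode_id=str(r.barcode_id),
                mean_lifespan=float(r.mean_lifespan),
                lifespan_cv=float(r.lifespan_cv),
                loss_frac_lo=float(r.loss_frac_lo),
                loss_frac_hi=float(r.loss_frac_hi),
                silencing_defect=bool(int(r.silencing_defect)),
                label=str(r.label),
            )
            for r in df.itertuples()
        )
        return cls(strains=strains, seed=seed)


@dataclass(frozen=True)
class DissectionSet:
    """Per-mother daughter counts for one genotype from bud dissection."""

    genotype: str
    lifespans: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.lifespans) < 1:
            raise ValueError("dissection set must contain at least one mother")
        if any(v < 0 for v in self.lifespans):
            raise ValueError("lifespans must be nonnegative integers")

    def __len__(self) -> int:
        return len(self.lifespans)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "genotype": self.genotype,
                "mother_id": np.arange(1, len(self.lifespans) + 1),
                "lifespan": list(self.lifespans),
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> list["DissectionSet"]:
        df = pd.read_csv(path, sep="\t")
        return [
            cls(genotype=str(g), lifespans=tuple(int(v) for v in sub["lifespan"]))
            for g, sub in df.groupby("genotype", sort=False)
        ]


@dataclass(frozen=True)
class ReproRecord:
    """One hermaphrodite's reproductive-span record.

    ``last_progeny_day`` is the final adulthood day with viable progeny
    (day 1 = first egg-laying day).  Sterile worms carry no day and are
    excluded from downstream curves and tests.
    """

    last_progeny_day: Optional[int]
    outcome: Optional[str]  # ceased | matricide | alive_at_end; None when sterile
    sterile: bool = False

    def __post_init__(self) -> None:
        if self.sterile:
            if self.last_progeny_day is not None:
                raise ValueError("sterile records carry no last_progeny_day")
        else:
            if self.last_progeny_day is None or self.last_progeny_day < 1:
                raise ValueError("last_progeny_day must be >= 1 for fertile worms")
            if self.outcome not in OUTCOMES:
                raise ValueError(f"unknown outcome {self.outcome!r}")


@dataclass(frozen=True)
class ReproSet:
    genotype: str
    records: tuple[ReproRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValueError("reproductive-span set must be nonempty")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def fertile(self) -> tuple[ReproRecord, ...]:
        return tuple(r for r in self.records if not r.sterile)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "genotype": self.genotype,
                "worm_id": np.arange(1, len(self.records) + 1),
                "last_progeny_day": [
                    "" if r.last_progeny_day is None else r.last_progeny_day
                    for r in self.records
                ],
                "outcome": [r.outcome or "" for r in self.records],
                "sterile": [int(r.sterile) for r in self.records],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> list["ReproSet"]:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        out = []
        for g, sub in df.groupby("genotype", sort=False):
            recs = []
            for r in sub.itertuples():
                sterile = bool(int(r.sterile))
                day = None if sterile or r.last_progeny_day == "" else int(float(r.last_progeny_day))
                outcome = None if sterile or r.outcome == "" else str(r.outcome)
                recs.append(ReproRecord(last_progeny_day=day, outcome=outcome, sterile=sterile))
            out.append(cls(genotype=str(g), records=tuple(recs)))
        return out


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_library(
    n_strains: int,
    frac_long: float,
    long_effect: float,
    frac_defective: float,
    base_lifespan: float,
    seed: int,
    lifespan_cv: float = DEFAULT_LIFESPAN_CV,
) -> Library:
    """Build a synthetic deletion library with planted long-lived and defective strains.

    ``round(frac_long * n_strains)`` strains get mean lifespan
    ``base_lifespan * (1 + long_effect)`` and label ``long_lived``;
    ``round(frac_defective * n_strains)`` get the stochastic silencing defect;
    the remainder are wildtype-like.  Label positions are shuffled with the
    seed so planted strains are not block-ordered.
    """
    if n_strains < 2:
        raise ValueError("n_strains must be >= 2")
    for name, v in (("frac_long", frac_long), ("frac_defective", frac_defective)):
        if not (np.isfinite(v) and 0 <= v <= 1):
            raise ValueError(f"{name} must be a finite fraction in [0, 1], got {v}")
    if frac_long + frac_defective > 1 + 1e-12:
        raise ValueError("frac_long + frac_defective must not exceed 1")
    if not (np.isfinite(long_effect) and long_effect > 0):
        raise ValueError("long_effect must be positive")
    if not (np.isfinite(base_lifespan) and base_lifespan > 0):
        raise ValueError("base_lifespan must be positive")

    n_long = round(frac_long * n_strains)
    n_def = round(frac_defective * n_strains)
    labels = np.array(
        ["long_lived"] * n_long
        + ["silencing_defective"] * n_def
        + ["wildtype_like"] * (n_strains - n_long - n_def),
        dtype=object,
    )
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)

    width = max(5, len(str(n_strains)))
    strains = []
    for i, lab in enumerate(labels):
        strains.append(
            StrainSpec(
                barcode_id=f"TAG{i + 1:0{width}d}",
                mean_lifespan=base_lifespan * (1 + long_effect)
                if lab == "long_lived"
                else base_lifespan,
                lifespan_cv=lifespan_cv,
                silencing_defect=(lab == "silencing_defective"),
                label=str(lab),
            )
        )
    return Library(strains=tuple(strains), seed=seed)


def sample_mother_lifespan(strain: StrainSpec, rng: np.random.Generator) -> int:
    """Draw one mother's replicative lifespan (nonnegative integer generations).

    The continuous law is a gamma with the strain's mean and CV (right-skewed,
    nonnegative, two-parameter), discretised by rounding and clipped at zero.
    ``lifespan_cv == 0`` collapses to ``round(mean_lifespan)``.
    """
    if strain.lifespan_cv == 0:
        return int(round(strain.mean_lifespan))
    shape = 1.0 / strain.lifespan_cv**2
    scale = strain.mean_lifespan * strain.lifespan_cv**2
    return int(max(0, round(rng.gamma(shape, scale))))


def loss_window(strain: StrainSpec, lifespan: int) -> tuple[int, int]:
    """Integer silencing-loss window ``(g_lo, g_hi)`` for a mother of this lifespan."""
    if lifespan <= 0:
        return (0, 0)
    g_lo = max(1, _ceil_tol(strain.loss_frac_lo * lifespan))
    g_hi = max(g_lo, min(lifespan, _floor_tol(strain.loss_frac_hi * lifespan)))
    g_lo = min(g_lo, lifespan)
    return (g_lo, g_hi)


def sample_loss_generation(
    strain: StrainSpec, lifespan: int, rng: np.random.Generator
) -> int:
    """Draw the division index at which this mother loses silencing.

    Non-defective strains draw uniformly from the integer window spanning
    70-100% (by default) of the mother's own lifespan, so a 30-generation
    mother derepresses somewhere in divisions 21..30.  Defective strains draw
    the first success of a constant per-division Bernoulli trial, which may
    fall anywhere (including past the lifespan: the mother then senesces
    silenced).
    """
    if lifespan < 0:
        raise ValueError("lifespan must be nonnegative")
    if strain.silencing_defect:
        return int(rng.geometric(strain.defect_loss_p))
    if lifespan == 0:
        return 0
    g_lo, g_hi = loss_window(strain, lifespan)
    return int(rng.integers(g_lo, g_hi + 1))


def make_dissection_set(
    strain: StrainSpec, n_mothers: int, seed: int, genotype: Optional[str] = None
) -> DissectionSet:
    """Simulate a bud-dissection experiment: independent per-mother lifespans."""
    if n_mothers < 1:
        raise ValueError("n_mothers must be >= 1")
    if n_mothers < 40:
        warnings.warn(
            f"n_mothers={n_mothers} is below the customary minimum of 40 founders",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    lifespans = tuple(sample_mother_lifespan(strain, rng) for _ in range(n_mothers))
    return DissectionSet(genotype=genotype or strain.barcode_id, lifespans=lifespans)


def default_matricide_hazard(
    rate: float, onset_day: int = 5, max_day: int = 60
) -> dict[int, float]:
    """Matricide hazard map: zero before the onset day, then constant.

    Matricide ("bagging") in aged hermaphrodites rises sharply from about
    day 5 of adulthood; this helper encodes that shape.
    """
    if not (0 <= rate <= 1):
        raise ValueError("rate must lie in [0, 1]")
    return {d: (rate if d >= onset_day else 0.0) for d in range(1, max_day + 1)}


def make_repro_set(
    mean_span: float,
    matricide_day_hazard: dict[int, float],
    sterile_frac: float,
    n_worms: int,
    seed: int,
    genotype: str = "synthetic",
    span_cv: float = 0.30,
    observe_days: Optional[int] = None,
) -> ReproSet:
    """Simulate per-worm reproductive spans with sterile and matricide outcomes.

    Each fertile worm draws a cessation day from a discretised gamma with the
    given mean (clipped at day 1).  While still reproducing, the worm may die
    of matricide on day ``d`` with probability ``matricide_day_hazard[d]``;
    matricide worms are reproductively active at removal.  Worms whose
    cessation day falls beyond ``observe_days`` (if given) are right-censored
    as ``alive_at_end``.
    """
    if not (0 <= sterile_frac < 1):
        raise ValueError("sterile_frac must lie in [0, 1)")
    if any(not (0 <= p <= 1) for p in matricide_day_hazard.values()):
        raise ValueError("matricide hazards must be probabilities")
    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    if not (np.isfinite(mean_span) and mean_span > 0):
        raise ValueError("mean_span must be positive")

    rng = np.random.default_rng(seed)
    records: list[ReproRecord] = []
    for _ in range(n_worms):
        if rng.random() < sterile_frac:
            records.append(ReproRecord(last_progeny_day=None, outcome=None, sterile=True))
            continue
        if span_cv == 0:
            cease = max(1, int(round(mean_span)))
        else:
            shape = 1.0 / span_cv**2
            cease = max(1, int(round(rng.gamma(shape, mean_span * span_cv**2))))
        day = None
        for d in range(1, cease):  # matricide can strike any still-reproducing day
            if rng.random() < matricide_day_hazard.get(d, 0.0):
                day = d
                break
        if day is not None:
            records.append(ReproRecord(last_progeny_day=day, outcome="matricide"))
        elif observe_days is not None and cease > observe_days:
            records.append(
                ReproRecord(last_progeny_day=observe_days, outcome="alive_at_end")
            )
        else:
            records.append(ReproRecord(last_progeny_day=cease, outcome="ceased"))
    return ReproSet(genotype=genotype, records=tuple(records))
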