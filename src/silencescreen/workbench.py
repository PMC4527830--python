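"""End-to-end screen runs, configuration, fixtures, and the manifest.

``run_paper_screen`` chains the whole pipeline the way the wet screen was
run: build the barcoded library, grow the query (aging reporter) and control
(constitutively silent reporter) pools with and without 5-FOA over the
16-day schedule, hybridize the paired cultures at the sampling days, apply
the hit rule and the control-library filter, and score the hit list against
the planted truth.  Every stochastic stage takes an explicit seed derived
from the master seed, all seeds are recorded in a manifest, and a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .arrays import (
    calls_to_frame,
    classify_long_lived,
    control_filter,
    normalize_log_ratios,
    recovery_report,
    simulate_hybridization,
)
from .screen import Schedule, run_screen
from .strains import (
    DissectionSet,
    StrainSpec,
    default_matricide_hazard,
    make_dissection_set,
    make_library,
    make_repro_set,
)

__all__ = ["RunConfig", "run_paper_screen", "make_fixtures"]

logger = logging.getLogger(__name__)

_STAGES = (
    "library",
    "sim_query_plus",
    "sim_query_minus",
    "sim_control_plus",
    "sim_control_minus",
    "hyb_query",
    "hyb_control",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything a full screen run needs, with the study-scale defaults."""

    n_strains: int = 3762
    frac_long: float = 52 / 3762
    long_effect: float = 0.4
    frac_defective: float = 0.02
    base_lifespan: float = 30.0
    lifespan_cv: float = 0.35
    noise_sd_log2: float = 0.25
    threshold: float = -2.3
    control_tolerance: float = 1.0
    seed: int = 1
    schedule: Schedule = field(default_factory=Schedule)

    def __post_init__(self) -> None:
        if self.threshold >= 0:
            raise ValueError("classification threshold must be negative")

    def stage_seeds(self) -> dict[str, int]:
        """One explicit sub-seed per stochastic stage, derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        states = ss.generate_state(len(_STAGES), dtype=np.uint64)
        return {name: int(s % (2**31)) for name, s in zip(_STAGES, states)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedule"] = dataclasses.asdict(self.schedule)
        d["schedule"]["sampling_days"] = list(self.schedule.sampling_days)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sched = d.pop("schedule", {})
        if "sampling_days" in sched:
            sched["sampling_days"] = tuple(sched["sampling_days"])
        return cls(schedule=Schedule(**sched), **d)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_paper_screen(config: RunConfig, outdir: str | Path) -> Path:
    """Run the full simulated screen and write all stage outputs.

    Writes the library, the four ±5-FOA trajectories (query and control
    reporters), normalized array samples, screen calls with labels, the
    recovery summary, and a manifest of seeds, config hash and version.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    stage = "library"
    try:
        lib = make_library(
            config.n_strains,
            config.frac_long,
            config.long_effect,
            config.frac_defective,
            config.base_lifespan,
            seed=seeds["library"],
            lifespan_cv=config.lifespan_cv,
        )
        lib.to_tsv(out / "library.tsv")
        n_long = sum(s.label == "long_lived" for s in lib.strains)
        n_def = sum(s.label == "silencing_defective" for s in lib.strains)
        logger.info(
            "library: %d strains in (%d long-lived, %d defective planted)",
            len(lib), n_long, n_def,
        )

        trajs = {}
        for stage, reporter, foa in (
            ("sim_query_plus", "hml", True),
            ("sim_query_minus", "hml", False),
            ("sim_control_plus", "mei4", True),
            ("sim_control_minus", "mei4", False),
        ):
            trajs[stage] = run_screen(
                lib, config.schedule, foa_on=foa, mode="expected",
                seed=seeds[stage], reporter=reporter,
            )
            trajs[stage].to_tsv(out / f"traj_{stage.removeprefix('sim_')}.tsv")
            logger.info("%s: sampled days %s", stage, trajs[stage].days)

        stage = "hyb_query"
        query_samples = {
            s.day: normalize_log_ratios(s)
            for s in simulate_hybridization(
                trajs["sim_query_plus"], trajs["sim_query_minus"],
                config.noise_sd_log2, seed=seeds["hyb_query"],
            )
        }
        stage = "hyb_control"
        control_samples = {
            s.day: normalize_log_ratios(s)
            for s in simulate_hybridization(
                trajs["sim_control_plus"], trajs["sim_control_minus"],
                config.noise_sd_log2, seed=seeds["hyb_control"],
            )
        }
        for name, samples in (("query", query_samples), ("control", control_samples)):
            import pandas as pd

            frames = []
            for day, s in sorted(samples.items()):
                f = s.data.copy()
                f.insert(0, "day", day)
                frames.append(f)
            pd.concat(frames, ignore_index=True).to_csv(
                out / f"arrays_{name}.tsv", sep="\t", index=False, float_format="%.10g"
            )

        stage = "classify"
        d6, d16 = sorted(query_samples)[:2] if len(query_samples) >= 2 else (None, None)
        calls = classify_long_lived(
            query_samples[d6], query_samples[d16], threshold=config.threshold
        )
        n_pre = sum(c.classified_long_lived for c in calls)
        calls = control_filter(
            calls, control_samples[d16], control_tolerance=config.control_tolerance
        )
        n_post = sum(c.classified_long_lived for c in calls)
        n_flag = sum(c.control_flagged for c in calls)
        logger.info(
            "classify: %d strains in, %d hits pre-filter, %d flagged, %d hits out",
            len(calls), n_pre, n_flag, n_post,
        )
        calls_to_frame(calls, lib).to_csv(
            out / "calls.tsv", sep="\t", index=False, float_format="%.10g"
        )

        stage = "recovery"
        rep = recovery_report(calls, lib)
        summary = {
            "n_strains": rep.n_strains,
            "n_planted_long_lived": rep.n_positive_truth,
            "n_classified": rep.n_classified,
            "tp": rep.tp, "fp": rep.fp, "fn": rep.fn, "tn": rep.tn,
            "sensitivity": float(rep.sensitivity),
            "specificity": float(rep.specificity),
            "precision": None if np.isnan(rep.precision) else float(rep.precision),
            "enrichment_p": float(rep.enrichment_p),
        }
        with open(out / "recovery.yaml", "w") as fh:
            yaml.safe_dump(summary, fh, sort_keys=True)

        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "stage_seeds": seeds,
        }
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"screen run failed at stage {stage!r}: {exc}") from exc
    return out


def make_fixtures(seed: int, outdir: str | Path) -> Path:
    """Write the small canonical TSV fixtures used by examples and tests.

    A 2-strain pool, 40-mother dissection sets targeting the published
    wild-type/mutant means (17.5 and 27.5 generations), and 25-worm
    reproductive-span sets matching the published group size.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed).generate_state(4, dtype=np.uint64)
    s_wt, s_mut, s_wtw, s_mutw = (int(s % 2**31) for s in ss)

    from .strains import Library

    lib = Library(
        (
            StrainSpec("TAG00001", 30.0, label="wildtype_like"),
            StrainSpec("TAG00002", 42.0, label="long_lived"),
        ),
        seed=seed,
    )
    lib.to_tsv(out / "pool2.tsv")

    wt = make_dissection_set(StrainSpec("WT", 17.5), 40, seed=s_wt, genotype="WT")
    mut = make_dissection_set(StrainSpec("mutant", 27.5), 40, seed=s_mut, genotype="mutant")
    wt.to_tsv(out / "rls_wt.tsv")
    mut.to_tsv(out / "rls_mutant.tsv")

    wt_worms = make_repro_set(
        4.5, default_matricide_hazard(0.05), sterile_frac=0.04, n_worms=25,
        seed=s_wtw, genotype="N2",
    )
    mut_worms = make_repro_set(
        7.5, default_matricide_hazard(0.15), sterile_frac=0.04, n_worms=25,
        seed=s_mutw, genotype="mutant",
    )
    wt_worms.to_tsv(out / "repro_wt.tsv")
    mut_worms.to_tsv(out / "repro_mutant.tsv")
    return out
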