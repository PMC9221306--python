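"""Synthetic behavioral, olfactory and DE data with planted ground truth.

The generator emulates the statistical structure the analyses assume, so
every pipeline stage can be exercised and power-checked without any
external data:

* **Ethograms** — each male's courtship fraction is Beta-distributed
  (mean = strain naive mean, variance set by one concentration parameter);
  training multiplies the mean by a per-timepoint suppression multiplier
  in [0, 1], so the expected learning index is 100*(1 - multiplier).
  Bouts are laid down as an alternating renewal (exponential on/off)
  process rescaled to hit the drawn fraction exactly within the window.
* **Strain profiles** — three built-ins reproduce the study's qualitative
  phenotypes: a control-like learner (suppression at every time point), a
  CBS-deletion-like non-learner (multiplier 1 everywhere) and a
  CSE-deletion-like strain that learns and retains at day 2 but has lost
  retention by day 8.
* **Olfactory replicates** — binomial counts of attracted flies per
  T-maze run (defaults: 15 flies/replicate, 31 replicates).
* **DE tables** — per-gene z-scores (null N(0,1), planted N(+-6,1) within
  designated annotation terms) converted to p-values, BH-FDR within each
  table, logFC centred at +-effect for planted genes; planted genes are
  sign-concordant across the replicate contrasts.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .deg_concordance import DETable, GeneSetAnnotation
from .ethogram_io import Bout, MaleObservation
from .olfactory_assay import OlfactoryReplicate


class SynthError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class StrainProfile:
    """Behavioral phenotype of one synthetic strain.

    ``suppression_by_timepoint`` maps a timepoint label to the multiplier
    applied to the trained males' courtship propensity: 1 = no learning
    (expected LI 0), m = expected LI 100*(1-m).
    """

    name: str
    naive_ci_mean: float = 50.0          # percent of the window
    naive_ci_concentration: float = 10.0  # Beta concentration (a+b)
    suppression_by_timepoint: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.naive_ci_mean < 100.0):
            raise SynthError(f"naive_ci_mean must be in (0,100), got {self.naive_ci_mean}")
        if self.naive_ci_concentration <= 0:
            raise SynthError("naive_ci_concentration must be positive")
        for tp, m in self.suppression_by_timepoint.items():
            if not (0.0 <= m <= 1.0):
                raise SynthError(f"multiplier {m} at {tp!r} outside [0,1]")

    def multiplier(self, timepoint: str) -> float:
        if timepoint not in self.suppression_by_timepoint:
            raise SynthError(f"{self.name}: no multiplier for timepoint {timepoint!r}")
        return self.suppression_by_timepoint[timepoint]

    def expected_li(self, timepoint: str) -> float:
        return 100.0 * (1.0 - self.multiplier(timepoint))


#: suppression multiplier of a learner; expected LI = 67
LEARNING_MULTIPLIER = 0.33
DEFAULT_TIMEPOINTS = ("0", "2", "8")  # days after training


def builtin_profiles(timepoints=DEFAULT_TIMEPOINTS) -> list[StrainProfile]:
    """The three study-like phenotypes over the given timepoint labels.

    control: learns and retains (multiplier 0.33 everywhere; LI ~ 67);
    cbs_like: never learns (multiplier 1; LI ~ 0);
    cse_like: learns and retains early, retention lost at the last
    timepoint (multiplier 1 there).
    """
    tps = tuple(timepoints)
    if not tps:
        raise SynthError("need at least one timepoint")
    return [
        StrainProfile(
            name="control",
            suppression_by_timepoint={tp: LEARNING_MULTIPLIER for tp in tps},
        ),
        StrainProfile(
            name="cbs_like",
            suppression_by_timepoint={tp: 1.0 for tp in tps},
        ),
        StrainProfile(
            name="cse_like",
            suppression_by_timepoint={
                tp: (1.0 if tp == tps[-1] else LEARNING_MULTIPLIER) for tp in tps
            },
        ),
    ]


@dataclass
class SynthConfig:
    """Study-shaped defaults: 20 males/group, 300-s window."""

    profiles: list[StrainProfile] = field(default_factory=builtin_profiles)
    n_males_per_group: int = 20
    window: float = 300.0
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    timepoint_unit: str = "days"
    seed: int = 0
    mean_bout_s: float = 10.0

    def __post_init__(self) -> None:
        if self.n_males_per_group < 1:
            raise SynthError(
                f"n_males_per_group must be >= 1, got {self.n_males_per_group}"
            )
        if self.window <= 0 or self.mean_bout_s <= 0:
            raise SynthError("window and mean_bout_s must be positive")


def _lay_bouts(
    rng: np.random.Generator, frac: float, window: float, mean_bout_s: float
) -> list[Bout]:
    """Alternating exponential on/off process rescaled to cover frac*window.

    On- and off-durations are drawn exponential and rescaled so courtship
    covers exactly ``frac * window`` (before millisecond rounding); the
    bout count is Poisson around frac*window/mean_bout_s, at least 1.
    """
    if frac <= 0.0:
        return []
    frac = min(frac, 1.0)
    target_on = frac * window
    n_bouts = max(1, int(rng.poisson(target_on / mean_bout_s)))
    on = rng.exponential(1.0, n_bouts)
    on *= target_on / on.sum()
    off = rng.exponential(1.0, n_bouts + 1)
    off_total = window - target_on
    off = off * (off_total / off.sum()) if off_total > 0 else np.zeros(n_bouts + 1)
    bouts = []
    t = 0.0
    for i in range(n_bouts):
        t += off[i]
        start = round(t, 3)
        t += on[i]
        end = round(min(t, window), 3)
        if end - start >= 1e-3:  # drop sub-millisecond slivers
            bouts.append(Bout(start, end))
    return bouts


def generate_ethograms(config: SynthConfig) -> list[MaleObservation]:
    """Simulate per-male ethograms for every profile x timepoint x condition."""
    rng = np.random.default_rng(config.seed)
    observations = []
    for profile in config.profiles:
        kappa = profile.naive_ci_concentration
        for tp in config.timepoints:
            mult = profile.multiplier(tp)
            for condition in ("naive", "trained"):
                mu = profile.naive_ci_mean / 100.0
                if condition == "trained":
                    mu *= mult
                for i in range(config.n_males_per_group):
                    frac = (
                        rng.beta(mu * kappa, (1.0 - mu) * kappa) if mu > 0 else 0.0
                    )
                    observations.append(
                        MaleObservation(
                            male_id=f"{profile.name}_d{tp}_{condition}_{i:04d}",
                            strain=profile.name,
                            condition=condition,
                            timepoint=tp,
                            timepoint_unit=config.timepoint_unit,
                            window=config.window,
                            bouts=_lay_bouts(rng, frac, config.window, config.mean_bout_s),
                        )
                    )
    return observations


def generate_olfactory(
    p_attract: float,
    n_flies_per_rep: int = 15,
    n_reps: int = 31,
    seed: int | None = None,
    genotype: str = "strain",
) -> list[OlfactoryReplicate]:
    """Binomial T-maze replicates: N_odor ~ Binomial(n_flies_per_rep, p)."""
    if not (0.0 <= p_attract <= 1.0):
        raise SynthError(f"p_attract must be in [0,1], got {p_attract}")
    if n_flies_per_rep < 1 or n_reps < 1:
        raise SynthError("n_flies_per_rep and n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.binomial(n_flies_per_rep, p_attract, size=n_reps)
    return [
        OlfactoryReplicate(
            replicate_id=f"{genotype}_rep{i + 1:02d}",
            genotype=genotype,
            n_odor=int(c),
            n_total=n_flies_per_rep,
        )
        for i, c in enumerate(counts)
    ]


def generate_de_tables(
    n_genes: int = 6000,
    contrasts: tuple[str, ...] = ("CBS_del_1", "CBS_del_2"),
    planted_terms: tuple[str, ...] = ("GO:0000001", "GO:0000002"),
    effect_logfc: float = 2.0,
    frac_down: float = 0.9,
    seed: int | None = None,
    n_terms: int = 20,
    term_size: int = 50,
    planted_fraction: float = 0.8,
    effect_z: float = 6.0,
) -> tuple[list[DETable], GeneSetAnnotation]:
    """DE tables with sign-concordant planted genes inside designated terms.

    Null genes: z ~ N(0,1), logFC ~ N(0, 0.25); planted genes (a
    ``planted_fraction`` of each planted term, the same genes in every
    contrast): z ~ N(effect_z, 1) and logFC centred at +-effect_logfc, with
    a ``frac_down`` share down-regulated.  p = 2*Phi(-|z|); FDR is BH
    within each table.
    """
    if n_genes < n_terms * 2:
        raise SynthError("n_genes too small for the requested annotation")
    if not (0.0 <= frac_down <= 1.0 and 0.0 < planted_fraction <= 1.0):
        raise SynthError("frac_down in [0,1] and planted_fraction in (0,1] required")
    rng = np.random.default_rng(seed)
    genes = np.array([f"FBgn{i:07d}" for i in range(n_genes)])

    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    unknown = set(planted_terms) - set(term_ids)
    if unknown:
        raise SynthError(f"planted terms {sorted(unknown)} not in the annotation")
    terms: dict[str, set[str]] = {}
    for term in term_ids:
        members = rng.choice(n_genes, size=min(term_size, n_genes), replace=False)
        terms[term] = set(genes[members])
    annotation = GeneSetAnnotation(terms=terms)

    planted: list[str] = []
    for term in planted_terms:
        members = sorted(terms[term])
        k = max(1, int(round(planted_fraction * len(members))))
        idx = rng.choice(len(members), size=k, replace=False)
        planted.extend(members[i] for i in idx)
    planted = sorted(set(planted))
    planted_idx = np.array(
        [int(g[4:]) for g in planted], dtype=np.intp
    )  # gene ids encode their index
    signs = np.where(rng.random(len(planted)) < frac_down, -1.0, 1.0)

    tables = []
    for contrast in contrasts:
        z = rng.normal(0.0, 1.0, n_genes)
        lfc = rng.normal(0.0, 0.25, n_genes)
        z[planted_idx] = signs * np.abs(rng.normal(effect_z, 1.0, len(planted)))
        lfc[planted_idx] = signs * np.abs(
            rng.normal(effect_logfc, 0.25, len(planted))
        )
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        df = pd.DataFrame(
            {"gene_id": genes, "logFC": lfc, "PValue": pvals, "FDR": fdr}
        )
        tables.append(DETable(contrast=contrast, data=df))
    return tables, annotation
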