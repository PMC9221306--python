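"""Learning indices and randomization inference for courtship conditioning.

The learning index of a strain at a time point is

    LI = (1 - mean(CI_tr) / mean(CI_na)) * 100

where CI_na and CI_tr are courtship indices of *independent* naive and
trained male cohorts.  LI = 0 means no suppression (no learning), LI = 100
complete suppression; negative values are possible.

Significance is assessed with two-sided randomization (permutation) tests
that directly estimate alpha_R, the probability of rejecting the null:

* ``randomization_two_sample`` — trained vs naive within a strain; the
  statistic is the difference of group means; group labels of the pooled
  CIs are exchangeable under H0.
* ``randomization_li_contrast`` — LI of strain A vs LI of strain B at the
  same time point; the statistic is LI_A - LI_B and the permutation is
  *stratified*: strain labels are shuffled among naive males and,
  independently, among trained males.  Training status is never permuted,
  because naive and trained cohorts are separate groups of flies and only
  the strain label is exchangeable under H0.
* ``retention_contrast`` — same machinery with strata = training status
  and the immediate/delayed occasion label permuted; used for the "memory
  retention lost at the delayed test" comparison.

Sampled mode estimates alpha_R = (b + 1) / (m + 1), where b counts permuted
|T| >= |T_obs| among m random label assignments — never exactly zero, which
keeps the test valid.  When the number of distinct assignments is small the
two-sample test enumerates them all and reports the exact tail proportion.
Ties (|T_perm| within 1e-12 of |T_obs|) count as extreme.

Defaults follow the study design: 10,000 permutations, rejection at
alpha_R < 0.05.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 10_000
DEFAULT_ALPHA = 0.05
#: auto-switch to exhaustive enumeration below this assignment count
DEFAULT_EXHAUSTIVE_THRESHOLD = 10_000
#: hard bound for exact enumeration
EXACT_MAX_ASSIGNMENTS = 200_000
#: |T| comparisons within this tolerance count as ties (extreme)
TIE_TOL = 1e-12

# generation cap for the zero-naive-mean redraw loop, as a multiple of n_perm
_MAX_REDRAW_FACTOR = 100


class StatsError(ValueError):
    """Raised for invalid samples or infeasible test configurations."""


@dataclass(frozen=True)
class LearningResult:
    """Learning index of one strain x timepoint, with the means behind it."""

    strain: str
    timepoint: str
    ci_na_mean: float
    ci_tr_mean: float
    li: float
    n_na: int
    n_tr: int


@dataclass(frozen=True)
class RandTestResult:
    """Outcome of one randomization test.

    ``alpha_r`` is the estimated probability of rejecting H0: in sampled
    mode (b+1)/(m+1); in exhaustive mode the exact proportion of label
    assignments with |T| >= |T_obs|.
    """

    statistic_observed: float
    alpha_r: float
    n_perm: int
    scheme: str  # {"two_sample", "li_contrast", "retention"}
    exhaustive: bool
    seed: int | None
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_r <= 1.0):
            raise StatsError(f"alpha_R {self.alpha_r} outside (0, 1]")


def _as_sample(values, name: str, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < min_n:
        raise StatsError(f"{name} must be a 1-D sample with at least {min_n} values")
    if not np.all(np.isfinite(arr)):
        raise StatsError(f"{name} contains non-finite values")
    return arr


def learning_index(
    ci_na, ci_tr, *, strain: str = "", timepoint: str = ""
) -> LearningResult:
    """LI = (1 - mean(CI_tr)/mean(CI_na)) * 100 from independent cohorts.

    Raises :class:`StatsError` when the naive males did not court at all
    (mean CI_na = 0), in which case LI is undefined.
    """
    na = _as_sample(ci_na, "ci_na")
    tr = _as_sample(ci_tr, "ci_tr")
    mean_na = float(na.mean())
    mean_tr = float(tr.mean())
    if mean_na <= 0.0:
        raise StatsError(
            f"LI undefined for {strain or 'group'}@{timepoint or '?'}: "
            "naive males did not court (mean CI_na = 0)"
        )
    li = (1.0 - mean_tr / mean_na) * 100.0
    return LearningResult(
        strain=strain,
        timepoint=timepoint,
        ci_na_mean=mean_na,
        ci_tr_mean=mean_tr,
        li=li,
        n_na=na.size,
        n_tr=tr.size,
    )


def _combination_count(n: int, m: int) -> int:
    return math.comb(n + m, n)


def _exact_mean_diff_tail(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Exact two-sided tail proportion for T = mean(x) - mean(y).

    Enumerates every way of assigning the pooled values to a group of size
    |x| (the complement gets size |y|); returns (proportion, n_assignments).
    """
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    total_sum = pooled.sum()
    t_obs = abs(x.mean() - y.mean())
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n + m), n)),
        dtype=np.intp,
    ).reshape(-1, n)
    sums = pooled[combos].sum(axis=1)
    t_perm = np.abs(sums / n - (total_sum - sums) / m)
    b = int(np.count_nonzero(t_perm >= t_obs - TIE_TOL))
    return b / combos.shape[0], combos.shape[0]


def exact_randomization(x, y, statistic=None) -> float:
    """Exact two-sided randomization p-value by full enumeration.

    ``statistic(x_part, y_part)`` defaults to the difference of means.  The
    returned value is the exact proportion of the C(|x|+|y|, |x|) label
    assignments whose |T| >= |T_obs| (ties extreme).  Refuses instances
    beyond 200,000 assignments; use the sampled test there.
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    n_assign = _combination_count(x.size, y.size)
    if n_assign > EXACT_MAX_ASSIGNMENTS:
        raise StatsError(
            f"{n_assign} assignments exceed the exact-enumeration bound "
            f"{EXACT_MAX_ASSIGNMENTS}; use randomization_two_sample (sampled)"
        )
    if statistic is None:
        p, _ = _exact_mean_diff_tail(x, y)
        return p
    pooled = np.concatenate([x, y])
    t_obs = abs(statistic(x, y))
    idx = np.arange(pooled.size)
    b = 0
    for combo in itertools.combinations(range(pooled.size), x.size):
        sel = np.zeros(pooled.size, dtype=bool)
        sel[list(combo)] = True
        t = abs(statistic(pooled[sel], pooled[~sel]))
        if t >= t_obs - TIE_TOL:
            b += 1
    del idx
    return b / n_assign


def _sampled_mean_diff_tail(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> int:
    """Count permuted |mean diff| >= |observed| over n_perm random relabelings."""
    n = x.size
    pooled = np.concatenate([x, y])
    t_obs = abs(x.mean() - y.mean())
    b = 0
    # chunked so memory stays modest at large n_perm
    chunk = 20_000
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        mat = np.tile(pooled, (k, 1))
        rng.permuted(mat, axis=1, out=mat)
        t_perm = np.abs(mat[:, :n].mean(axis=1) - mat[:, n:].mean(axis=1))
        b += int(np.count_nonzero(t_perm >= t_obs - TIE_TOL))
        done += k
    return b


def randomization_two_sample(
    x,
    y,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    *,
    exhaustive_threshold: int = DEFAULT_EXHAUSTIVE_THRESHOLD,
) -> RandTestResult:
    """Two-sided randomization test for a difference in group means.

    Pooled values are randomly reassigned to the two groups (sizes
    preserved); alpha_R = (b+1)/(m+1).  When C(|x|+|y|, |x|) <=
    ``exhaustive_threshold`` all assignments are enumerated instead and the
    exact tail proportion is reported with ``exhaustive=True``.
    """
    x = _as_sample(x, "x", min_n=2)
    y = _as_sample(y, "y", min_n=2)
    if n_perm < 1:
        raise StatsError(f"n_perm must be >= 1, got {n_perm}")
    t_obs = float(x.mean() - y.mean())
    n_assign = _combination_count(x.size, y.size)
    if n_assign <= exhaustive_threshold:
        p, total = _exact_mean_diff_tail(x, y)
        return RandTestResult(
            statistic_observed=t_obs,
            alpha_r=p,
            n_perm=total,
            scheme="two_sample",
            exhaustive=True,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    b = _sampled_mean_diff_tail(x, y, n_perm, rng)
    return RandTestResult(
        statistic_observed=t_obs,
        alpha_r=(b + 1) / (n_perm + 1),
        n_perm=n_perm,
        scheme="two_sample",
        exhaustive=False,
        seed=seed,
    )


def _li_from_means(na_mean: np.ndarray, tr_mean: np.ndarray) -> np.ndarray:
    return (1.0 - tr_mean / na_mean) * 100.0


def _stratified_li_diff_tail(
    na_a: np.ndarray,
    tr_a: np.ndarray,
    na_b: np.ndarray,
    tr_b: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    t_obs: float,
) -> tuple[int, int]:
    """Sampled stratified null for T = LI_A - LI_B.

    Strain labels are shuffled within the naive stratum and, independently,
    within the trained stratum.  Permutations in which either reconstructed
    naive group has mean CI 0 (LI undefined) are redrawn and counted.
    Returns (b, n_redrawn).
    """
    pooled_na = np.concatenate([na_a, na_b])
    pooled_tr = np.concatenate([tr_a, tr_b])
    k_na, k_tr = na_a.size, tr_a.size
    t_abs = abs(t_obs)
    b = 0
    filled = 0
    redrawn = 0
    while filled < n_perm:
        k = min(20_000, n_perm - filled)
        mat_na = np.tile(pooled_na, (k, 1))
        rng.permuted(mat_na, axis=1, out=mat_na)
        mat_tr = np.tile(pooled_tr, (k, 1))
        rng.permuted(mat_tr, axis=1, out=mat_tr)
        na_mean_a = mat_na[:, :k_na].mean(axis=1)
        na_mean_b = mat_na[:, k_na:].mean(axis=1)
        tr_mean_a = mat_tr[:, :k_tr].mean(axis=1)
        tr_mean_b = mat_tr[:, k_tr:].mean(axis=1)
        valid = (na_mean_a > 0) & (na_mean_b > 0)
        n_valid = int(np.count_nonzero(valid))
        redrawn += k - n_valid
        if redrawn > _MAX_REDRAW_FACTOR * n_perm:
            raise StatsError(
                "stratified permutation cannot avoid zero naive means "
                "(too many zero CIs in the pooled naive stratum)"
            )
        t_perm = np.abs(
            _li_from_means(na_mean_a[valid], tr_mean_a[valid])
            - _li_from_means(na_mean_b[valid], tr_mean_b[valid])
        )
        b += int(np.count_nonzero(t_perm >= t_abs - TIE_TOL))
        filled += n_valid
    return b, redrawn


def _li_contrast(
    group_a: tuple,
    group_b: tuple,
    n_perm: int,
    seed: int | None,
    scheme: str,
) -> RandTestResult:
    na_a = _as_sample(group_a[0], "group_a naive")
    tr_a = _as_sample(group_a[1], "group_a trained")
    na_b = _as_sample(group_b[0], "group_b naive")
    tr_b = _as_sample(group_b[1], "group_b trained")
    if n_perm < 1:
        raise StatsError(f"n_perm must be >= 1, got {n_perm}")
    li_a = learning_index(na_a, tr_a).li
    li_b = learning_index(na_b, tr_b).li
    t_obs = li_a - li_b
    rng = np.random.default_rng(seed)
    b, redrawn = _stratified_li_diff_tail(na_a, tr_a, na_b, tr_b, n_perm, rng, t_obs)
    if redrawn > 0.01 * n_perm:
        logger.warning(
            "%s: %d/%d stratified permutations redrawn for zero naive means",
            scheme,
            redrawn,
            n_perm,
        )
    return RandTestResult(
        statistic_observed=t_obs,
        alpha_r=(b + 1) / (n_perm + 1),
        n_perm=n_perm,
        scheme=scheme,
        exhaustive=False,
        seed=seed,
        n_redrawn=redrawn,
    )


def randomization_li_contrast(
    group_a: tuple,
    group_b: tuple,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> RandTestResult:
    """Randomization test for LI_A - LI_B between two strains.

    ``group_a`` and ``group_b`` are ``(ci_na, ci_tr)`` pairs of samples.
    The null shuffles strain labels within the naive and trained strata
    separately (training status is never permuted).
    """
    return _li_contrast(group_a, group_b, n_perm, seed, "li_contrast")


def retention_contrast(
    strain_immediate: tuple,
    strain_delayed: tuple,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> RandTestResult:
    """Randomization test for LI(delayed) - LI(immediate) within one strain.

    Identical machinery to :func:`randomization_li_contrast` with strata =
    training status and the immediate/delayed occasion label permuted; used
    to flag loss of memory retention at delayed tests.
    """
    return _li_contrast(strain_delayed, strain_immediate, n_perm, seed, "retention")


@dataclass
class TimecourseConfig:
    """Knobs of the full LI timecourse analysis (defaults = study values)."""

    n_perm: int = DEFAULT_N_PERM
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    #: apply a Bonferroni factor over the contrasts of the table when flagging
    bonferroni: bool = False


def _timepoint_sort_key(tp: str):
    try:
        return (0, float(tp), tp)
    except ValueError:
        return (1, 0.0, tp)


def li_timecourse(
    groups,
    control_strains: list[str],
    config: TimecourseConfig | None = None,
) -> pd.DataFrame:
    """One row per strain x timepoint: LI plus the three contrast families.

    Per row: alpha_within (trained vs naive two-sample randomization),
    alpha_vs_<control> (stratified LI contrast against each control strain at
    the same time point) and alpha_retention (delayed vs earliest time point
    of the same strain).  Flags mirror the figure annotations at
    alpha_R < alpha: ``*``/``&`` when the strain LI is significantly lower
    than the first/second control, ``#`` when retention is significantly
    lower than at the earliest time point.  Missing naive or trained cohorts
    yield a row with status ``not_testable``.
    """
    if config is None:
        config = TimecourseConfig()
    cells: dict[tuple[str, str, str], dict[str, "GroupSample"]] = {}
    strains: list[str] = []
    for g in groups:
        cell = cells.setdefault((g.strain, g.timepoint, g.timepoint_unit), {})
        if g.condition in cell:
            raise StatsError(f"duplicate group for {g.key}")
        cell[g.condition] = g
        if g.strain not in strains:
            strains.append(g.strain)

    timepoints = sorted(
        {(tp, unit) for (_, tp, unit) in cells}, key=lambda t: _timepoint_sort_key(t[0])
    )
    seed_seq = np.random.SeedSequence(config.seed)

    def next_seed() -> int:
        child = seed_seq.spawn(1)[0]
        return int(child.generate_state(1)[0] & 0x7FFFFFFF)

    n_tests = 0
    rows = []
    for strain in strains:
        baseline: tuple | None = None  # (timepoint, (na, tr)) earliest testable
        for tp, unit in timepoints:
            cell = cells.get((strain, tp, unit))
            if cell is None:
                continue
            row: dict = {
                "strain": strain,
                "timepoint": tp,
                "timepoint_unit": unit,
            }
            na = cell.get("naive")
            tr = cell.get("trained")
            row["n_na"] = na.n if na else 0
            row["n_tr"] = tr.n if tr else 0
            if na is None or tr is None or np.mean(na.cis) <= 0:
                row.update(
                    ci_na_mean=np.nan,
                    ci_tr_mean=np.nan,
                    li=np.nan,
                    alpha_within=np.nan,
                    alpha_retention=np.nan,
                    flags="",
                    status="not_testable",
                )
                for ctrl in control_strains:
                    if ctrl != strain:
                        row[f"alpha_vs_{ctrl}"] = np.nan
                rows.append(row)
                continue

            lr = learning_index(na.cis, tr.cis, strain=strain, timepoint=tp)
            row.update(
                ci_na_mean=lr.ci_na_mean, ci_tr_mean=lr.ci_tr_mean, li=lr.li
            )
            res_within = randomization_two_sample(
                na.cis, tr.cis, n_perm=config.n_perm, seed=next_seed()
            )
            row["alpha_within"] = res_within.alpha_r
            n_tests += 1

            flags = ""
            for marker, ctrl in zip("*&", control_strains):
                if ctrl == strain:
                    continue
                ctrl_cell = cells.get((ctrl, tp, unit), {})
                c_na, c_tr = ctrl_cell.get("naive"), ctrl_cell.get("trained")
                col = f"alpha_vs_{ctrl}"
                if c_na is None or c_tr is None or np.mean(c_na.cis) <= 0:
                    row[col] = np.nan
                    continue
                res = randomization_li_contrast(
                    (na.cis, tr.cis),
                    (c_na.cis, c_tr.cis),
                    n_perm=config.n_perm,
                    seed=next_seed(),
                )
                row[col] = res.alpha_r
                n_tests += 1
                ctrl_li = learning_index(c_na.cis, c_tr.cis).li
                if res.alpha_r < config.alpha and lr.li < ctrl_li:
                    flags += marker

            if baseline is None:
                row["alpha_retention"] = np.nan
            else:
                base_tp, base_samples, base_li = baseline
                res = retention_contrast(
                    base_samples,
                    (na.cis, tr.cis),
                    n_perm=config.n_perm,
                    seed=next_seed(),
                )
                row["alpha_retention"] = res.alpha_r
                n_tests += 1
                if res.alpha_r < config.alpha and lr.li < base_li:
                    flags += "#"
            if baseline is None:
                baseline = (tp, (na.cis, tr.cis), lr.li)

            row["flags"] = flags
            row["status"] = "ok"
            rows.append(row)

    columns = ["strain", "timepoint", "timepoint_unit", "n_na", "n_tr",
               "ci_na_mean", "ci_tr_mean", "li", "alpha_within"]
    columns += [f"alpha_vs_{c}" for c in control_strains]
    columns += ["alpha_retention", "flags", "status"]
    df = pd.DataFrame(rows, columns=columns)
    if config.bonferroni and n_tests > 1:
        # flags were decided at the per-contrast alpha; re-derive at alpha/k
        logger.info("Bonferroni over %d contrasts: flag threshold %g",
                    n_tests, config.alpha / n_tests)
        df = _reflag(df, control_strains, config.alpha / n_tests)
    return df


def _reflag(df: pd.DataFrame, control_strains: list[str], alpha: float) -> pd.DataFrame:
    df = df.copy()
    li_by_key = {
        (r.strain, r.timepoint): r.li for r in df.itertuples() if r.status == "ok"
    }
    base_li: dict[str, float] = {}
    for r in df.itertuples():
        if r.status == "ok" and r.strain not in base_li:
            base_li[r.strain] = r.li
    flags = []
    for r in df.itertuples():
        if r.status != "ok":
            flags.append("")
            continue
        f = ""
        for marker, ctrl in zip("*&", control_strains):
            if ctrl == r.strain:
                continue
            a = getattr(r, f"alpha_vs_{ctrl}", np.nan)
            ctrl_li = li_by_key.get((ctrl, r.timepoint), np.nan)
            if np.isfinite(a) and a < alpha and r.li < ctrl_li:
                f += marker
        if np.isfinite(r.alpha_retention) and r.alpha_retention < alpha and r.li < base_li[r.strain]:
            f += "#"
        flags.append(f)
    df["flags"] = flags
    return df


def write_timecourse(df: pd.DataFrame, path) -> None:
    """Write the timecourse table as TSV with stable float formatting."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
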