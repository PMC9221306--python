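"""T-maze olfactory preference index and nonparametric genotype comparison.

Each replicate releases ~15 naive males into a T-maze offering an
odorant-laden arm versus fresh air; the preference index is

    V(%) = 100 * N_odor / N_total

the percentage of flies attracted (non-repulsed) by the odorant.  The
replicate — not the individual fly — is the unit of analysis, and genotypes
are compared to the control with a two-sided Mann-Whitney U test (always
nonparametric; V distributions from strongly repulsive odorants are far
from normal).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

OLFACTORY_COLUMNS = ["replicate_id", "genotype", "n_odor", "n_total"]

#: exact Mann-Whitney in auto mode up to this many rank assignments
MWU_EXACT_THRESHOLD = 20_000


class OlfactoryError(ValueError):
    """Raised for invalid counts or malformed replicate files."""


def preference_index(n_odor: int, n_total: int) -> float:
    """V(%) = 100 * N_odor / N_total, in [0, 100]."""
    if n_total < 1:
        raise OlfactoryError(f"n_total must be >= 1, got {n_total}")
    if not (0 <= n_odor <= n_total):
        raise OlfactoryError(f"n_odor={n_odor} outside [0, n_total={n_total}]")
    return 100.0 * n_odor / n_total


@dataclass(frozen=True)
class OlfactoryReplicate:
    """One T-maze run: counts and the derived preference index V."""

    replicate_id: str
    genotype: str
    n_odor: int
    n_total: int

    def __post_init__(self) -> None:
        preference_index(self.n_odor, self.n_total)  # validates

    @property
    def v(self) -> float:
        return preference_index(self.n_odor, self.n_total)


@dataclass(frozen=True)
class MwuResult:
    u: float
    pvalue: float
    method: str  # "exact" | "asymptotic" | "degenerate"


def mwu_test(x, y, mode: str = "auto") -> MwuResult:
    """Two-sided Mann-Whitney U test.

    U counts pairs (x_i, y_j) with x_i > y_j plus half the tied pairs.
    ``mode="exact"`` enumerates the null rank distribution (refuses ties,
    falling back to the asymptotic path with a log line); ``"approx"`` uses
    the normal approximation with midranks, tie-corrected variance and
    continuity correction; ``"auto"`` picks exact when there are no ties and
    C(|x|+|y|, |x|) <= 20,000.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise OlfactoryError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise OlfactoryError(f"unknown mode {mode!r}")

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    # all-tied pooled sample: the tie-corrected variance is zero and the
    # normal approximation degenerates; by symmetry p = 1
    if np.unique(pooled).size == 1:
        return MwuResult(u=x.size * y.size / 2.0, pvalue=1.0, method="degenerate")

    use_exact = False
    if mode == "exact":
        if has_ties:
            logger.info("mwu_test: ties present, exact mode falls back to asymptotic")
        else:
            use_exact = True
    elif mode == "auto":
        use_exact = not has_ties and math.comb(x.size + y.size, x.size) <= MWU_EXACT_THRESHOLD

    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    p = float(min(res.pvalue, 1.0))
    if not p > 0.0:
        p = np.nextafter(0.0, 1.0)
    return MwuResult(u=float(res.statistic), pvalue=p, method=method)


def read_olfactory(path) -> list[OlfactoryReplicate]:
    """Read the replicate CSV (replicate_id, genotype, n_odor, n_total)."""
    replicates = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            c for c in OLFACTORY_COLUMNS if c not in reader.fieldnames
        ]:
            raise OlfactoryError(
                f"{path}: missing or malformed header; expected {','.join(OLFACTORY_COLUMNS)}"
            )
        for line_no, row in enumerate(reader, start=2):
            try:
                rep = OlfactoryReplicate(
                    replicate_id=row["replicate_id"].strip(),
                    genotype=row["genotype"].strip(),
                    n_odor=int(row["n_odor"]),
                    n_total=int(row["n_total"]),
                )
            except (ValueError, TypeError) as exc:
                raise OlfactoryError(f"{path}: line {line_no}: {exc}") from None
            replicates.append(rep)
    return replicates


def write_olfactory(replicates: list[OlfactoryReplicate], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(OLFACTORY_COLUMNS)
        for r in replicates:
            writer.writerow([r.replicate_id, r.genotype, r.n_odor, r.n_total])


def olfactory_report(
    replicates: list[OlfactoryReplicate], control: str, mode: str = "auto"
) -> pd.DataFrame:
    """Per-genotype V summary (median, IQR, n) and Mann-Whitney p vs control.

    Genotypes with fewer than 2 replicates are summarized but reported
    ``untested``; the control row carries no p-value.
    """
    by_geno: dict[str, list[float]] = {}
    order: list[str] = []
    for r in replicates:
        by_geno.setdefault(r.genotype, []).append(r.v)
        if r.genotype not in order:
            order.append(r.genotype)
    if control not in by_geno:
        raise OlfactoryError(f"control genotype {control!r} not present")
    ctrl_v = np.asarray(by_geno[control])

    rows = []
    for geno in order:
        v = np.asarray(by_geno[geno])
        row = {
            "genotype": geno,
            "n_replicates": v.size,
            "median_v": float(np.median(v)),
            "q1_v": float(np.percentile(v, 25)),
            "q3_v": float(np.percentile(v, 75)),
        }
        if geno == control:
            row.update(u=np.nan, p_vs_control=np.nan, status="control")
        elif v.size < 2 or ctrl_v.size < 2:
            row.update(u=np.nan, p_vs_control=np.nan, status="untested")
        else:
            res = mwu_test(v, ctrl_v, mode=mode)
            row.update(u=res.u, p_vs_control=res.pvalue, status="tested")
        rows.append(row)
    return pd.DataFrame(rows)
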