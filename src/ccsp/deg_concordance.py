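"""Post-differential-expression set analytics across deletion strains.

Consumes per-contrast DE result tables (gene, log2 fold change, p-value,
BH FDR — e.g. edgeR output) and provides:

* direction-aware significant-gene selection (FDR < threshold);
* concordant ("similar pattern") genes across replicate strains — by
  default the strict rule: significant in *every* table with the same
  logFC sign everywhere (a lenient rule — significant in at least one
  table, sign-concordant in all — is available, since either reading fits
  typical phrasing of replicate-strain agreement);
* Venn partitioning of up to four named gene sets;
* one-sided Fisher exact enrichment of a study set against a flat
  gene→term annotation, BH-adjusted across terms, with the dot-plot
  metrics (mean logFC over significant term genes, proportion of the term
  altered);
* the qPCR delta-delta-Ct fold change, 2^-ddCt, normalized to a
  housekeeping reference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene_id", "logFC", "PValue", "FDR"]
DEFAULT_FDR = 0.05


class DegError(ValueError):
    """Raised for malformed DE tables, annotations, or set inputs."""


@dataclass
class DETable:
    """One strain-vs-control DE contrast: gene_id -> (logFC, PValue, FDR)."""

    contrast: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DE_COLUMNS if c not in self.data.columns]
        if missing:
            raise DegError(f"{self.contrast}: missing DE columns {missing}")
        if self.data["gene_id"].duplicated().any():
            dup = self.data.loc[self.data["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise DegError(f"{self.contrast}: duplicate gene_id {dup!r}")
        fdr = self.data["FDR"].to_numpy()
        if np.any((fdr < 0) | (fdr > 1) | ~np.isfinite(fdr)):
            raise DegError(f"{self.contrast}: FDR values outside [0, 1]")
        if not np.all(np.isfinite(self.data["logFC"].to_numpy())):
            raise DegError(f"{self.contrast}: non-finite logFC")
        self.data = self.data.reset_index(drop=True)

    @property
    def genes(self) -> set[str]:
        return set(self.data["gene_id"])


@dataclass
class GeneSetAnnotation:
    """Flat gene-set annotation: term_id -> set of gene_ids (no GO-graph
    propagation; terms are taken as given)."""

    terms: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise DegError(f"annotation term {term!r} is empty")

    @property
    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return out


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's Fisher enrichment plus the dot-plot display metrics."""

    term_id: str
    k: int      # study genes in term
    K: int      # term size within the universe
    n: int      # study-set size
    N: int      # universe size
    p: float    # one-sided (enrichment) Fisher exact
    q: float    # BH-adjusted across tested terms
    mean_logfc: float  # mean logFC over significant term genes (NaN if none)
    prop_altered: float


def read_de_table(path, contrast: str | None = None) -> DETable:
    """Read a DE TSV (gene_id, logFC, PValue, FDR)."""
    df = pd.read_csv(path, sep="\t")
    name = contrast if contrast is not None else str(path)
    return DETable(contrast=name, data=df)


def write_de_table(table: DETable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_annotation(path) -> GeneSetAnnotation:
    """Read a gene→term TSV (gene_id, term_id[, term_name])."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "term_id" not in df.columns:
        raise DegError(f"{path}: annotation needs gene_id and term_id columns")
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        terms.setdefault(row.term_id, set()).add(row.gene_id)
        if "term_name" in df.columns and isinstance(row.term_name, str):
            names[row.term_id] = row.term_name
    return GeneSetAnnotation(terms=terms, names=names)


def write_annotation(annotation: GeneSetAnnotation, path) -> None:
    rows = []
    for term in sorted(annotation.terms):
        for gene in sorted(annotation.terms[term]):
            rows.append((gene, term, annotation.names.get(term, "")))
    pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"]).to_csv(
        path, sep="\t", index=False
    )


def significant_genes(
    table: DETable, fdr_threshold: float = DEFAULT_FDR, direction: str = "any"
) -> set[str]:
    """Genes with FDR < threshold whose logFC sign matches ``direction``."""
    if not (0.0 < fdr_threshold < 1.0):
        raise DegError(f"fdr_threshold must be in (0,1), got {fdr_threshold}")
    if direction not in ("up", "down", "any"):
        raise DegError(f"unknown direction {direction!r}")
    sig = table.data["FDR"].to_numpy() < fdr_threshold
    lfc = table.data["logFC"].to_numpy()
    if direction == "down":
        sig &= lfc < 0
    elif direction == "up":
        sig &= lfc > 0
    return set(table.data.loc[sig, "gene_id"])


def consistent_genes(
    tables: list[DETable],
    fdr_threshold: float = DEFAULT_FDR,
    direction: str = "any",
    mode: str = "strict",
) -> set[str]:
    """Genes showing the same expression change across replicate contrasts.

    strict (default): significant (FDR < threshold, matching direction) in
    every table, with an identical logFC sign across all tables.
    lenient: significant in at least one table, present in every table and
    sign-concordant everywhere.
    Genes absent from any table are excluded (logged).
    """
    if len(tables) < 2:
        raise DegError("consistent_genes needs at least 2 tables")
    if mode not in ("strict", "lenient"):
        raise DegError(f"unknown mode {mode!r}")
    sig_sets = [significant_genes(t, fdr_threshold, direction) for t in tables]
    gene_sets = [t.genes for t in tables]
    shared = set.intersection(*gene_sets)
    candidates = set.intersection(*sig_sets) if mode == "strict" else set.union(*sig_sets)
    n_absent = len(candidates - shared)
    if n_absent:
        logger.info(
            "consistent_genes: %d candidate gene(s) absent from some table, excluded",
            n_absent,
        )
    candidates &= shared
    signs = [
        dict(zip(t.data["gene_id"], np.sign(t.data["logFC"].to_numpy())))
        for t in tables
    ]
    out = set()
    for gene in candidates:
        s = {signmap[gene] for signmap in signs}
        if len(s) == 1 and 0 not in s:
            out.add(gene)
    return out


def venn_partition(named_sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Counts of every membership region of 1-4 named sets.

    Returns all 2^k - 1 regions keyed by the sorted tuple of member set
    names; regions are disjoint and their counts sum to the union size.
    """
    if not (1 <= len(named_sets) <= 4):
        raise DegError("venn_partition takes 1-4 named sets")
    names = list(named_sets)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set.intersection(*(named_sets[m] for m in members))
            outside = set().union(
                *(named_sets[m] for m in names if m not in members), set()
            )
            regions[tuple(members)] = len(inside - outside)
    return regions


def _fisher_enrichment_p(k: int, K: int, n: int, N: int) -> float:
    """One-sided Fisher exact (enrichment) for the 2x2 table
    [[k, n-k], [K-k, N-K-n+k]]; equals the upper hypergeometric tail."""
    if not (0 <= k <= min(K, n) and max(K, n) <= N):
        raise DegError(f"inconsistent 2x2 counts k={k} K={K} n={n} N={N}")
    table = [[k, n - k], [K - k, N - K - n + k]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(min(p, 1.0))


def fisher_enrichment(
    study_set: set[str],
    annotation: GeneSetAnnotation,
    universe: set[str],
    fdr_threshold: float = DEFAULT_FDR,
    table: DETable | None = None,
) -> list[EnrichmentRow]:
    """Per-term one-sided Fisher enrichment of ``study_set`` within ``universe``.

    Terms are intersected with the universe first; empty-after-restriction
    terms are dropped with a log line.  q is BH across the tested terms.
    When a DE ``table`` is supplied, rows carry the dot-plot metrics (mean
    logFC over the term's significant genes and the proportion of the term
    altered at FDR < threshold).
    """
    if not study_set <= universe:
        raise DegError("study_set must be a subset of the universe")
    n = len(study_set)
    N = len(universe)
    metrics = (
        term_dot_metrics(table, annotation, fdr_threshold) if table is not None else {}
    )
    raw: list[tuple[str, int, int, float]] = []
    for term in sorted(annotation.terms):
        term_genes = annotation.terms[term] & universe
        K = len(term_genes)
        if K == 0:
            logger.info("term %s empty after universe restriction, dropped", term)
            continue
        k = len(term_genes & study_set)
        raw.append((term, k, K, _fisher_enrichment_p(k, K, n, N)))
    if not raw:
        return []
    pvals = [r[3] for r in raw]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    rows = []
    for (term, k, K, p), q in zip(raw, qvals):
        mean_lfc, prop = metrics.get(term, (np.nan, np.nan))
        rows.append(
            EnrichmentRow(
                term_id=term, k=k, K=K, n=n, N=N, p=p, q=float(min(q, 1.0)),
                mean_logfc=mean_lfc, prop_altered=prop,
            )
        )
    return rows


def term_dot_metrics(
    table: DETable,
    annotation: GeneSetAnnotation,
    fdr_threshold: float = DEFAULT_FDR,
) -> dict[str, tuple[float, float]]:
    """Per-term (mean logFC of significant genes, fraction significant).

    ``mean_logfc`` averages logFC over the term's genes at FDR < threshold
    (NaN when the term has none); ``prop_altered`` divides that count by the
    term size restricted to the table's genes.
    """
    sig = significant_genes(table, fdr_threshold, "any")
    lfc = dict(zip(table.data["gene_id"], table.data["logFC"]))
    table_genes = table.genes
    out: dict[str, tuple[float, float]] = {}
    for term, genes in annotation.terms.items():
        present = genes & table_genes
        if not present:
            continue
        sig_genes = present & sig
        prop = len(sig_genes) / len(present)
        mean_lfc = (
            float(np.mean([lfc[g] for g in sorted(sig_genes)])) if sig_genes else np.nan
        )
        out[term] = (mean_lfc, prop)
    return out


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "q": r.q,
                "mean_logfc": r.mean_logfc,
                "prop_altered": r.prop_altered,
            }
            for r in rows
        ],
        columns=["term_id", "k", "K", "n", "N", "p", "q", "mean_logfc", "prop_altered"],
    )


def ddct_fold_change(
    ct_target_sample,
    ct_ref_sample,
    ct_target_control,
    ct_ref_control,
) -> float:
    """Relative expression by the delta-delta-Ct method: 2^-ddCt.

    ddCt = (Ct_target,sample - Ct_ref,sample) - (Ct_target,control -
    Ct_ref,control); the reference is a housekeeping gene (rp49 in fly
    head qPCR).  Samples may be scalars or replicate arrays (averaged).
    """
    cts = [
        float(np.mean(np.asarray(v, dtype=float)))
        for v in (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control)
    ]
    if not all(np.isfinite(cts)):
        raise DegError("Ct values must be finite")
    ddct = (cts[0] - cts[1]) - (cts[2] - cts[3])
    return float(2.0 ** (-ddct))
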