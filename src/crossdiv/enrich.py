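"""Divergence-tail extraction, gene-set overlaps, and functional enrichment.

The characterization stage asks which genes sit in the extreme low or high
2.5% of each (taxon, level) divergence ranking, how much those sets
overlap across levels (with a random-sampling baseline for calibration),
and which annotation terms are over-represented in each set against a
genome-wide background (upper-tail hypergeometric test with
Benjamini-Hochberg false-discovery-rate control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError, ConfigError

DEFAULT_TAIL_FRACTION = 0.025


@dataclass(frozen=True)
class GeneSetPartition:
    """Low- and high-divergence tail gene sets for one (taxon, level)."""

    taxon: str
    level: str
    k: int
    low_set: frozenset[str]
    high_set: frozenset[str]


@dataclass(frozen=True)
class OverlapSummary:
    """Counts of the seven exclusive Venn regions of three gene sets.

    Region keys follow membership: ``seq_only``, ``expr_only``,
    ``struct_only``, ``seq_expr``, ``seq_struct``, ``expr_struct``,
    ``all_three``.
    """

    taxon: str
    tail: str
    seq_only: int
    expr_only: int
    struct_only: int
    seq_expr: int
    seq_struct: int
    expr_struct: int
    all_three: int

    @property
    def triple_intersection(self) -> int:
        return self.all_three


class AnnotationMap:
    """Gene-to-term annotations over a genome-wide background."""

    def __init__(self, annotations: Mapping[str, Iterable[str]], background: Iterable[str]):
        self.background = frozenset(map(str, background))
        clean: dict[str, frozenset[str]] = {}
        for gene, terms in annotations.items():
            gene = str(gene)
            if gene not in self.background:
                raise ConfigError(f"annotated gene {gene!r} missing from background")
            clean[gene] = frozenset(map(str, terms))
        self.annotations = clean

    @classmethod
    def from_tsv(cls, source, background: Iterable[str] | None = None) -> "AnnotationMap":
        """Read a two-column TSV (gene, term), one pair per line.

        Without an explicit background, the annotated genes serve as the
        background.
        """
        from .io import _read_lines  # shared line reader

        pairs: list[tuple[str, str]] = []
        for lineno, line in enumerate(_read_lines(source), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ConfigError(f"annotation row {lineno}: expected 2 fields, got {len(parts)}")
            pairs.append((parts[0], parts[1]))
        anno: dict[str, set[str]] = {}
        for gene, term in pairs:
            anno.setdefault(gene, set()).add(term)
        bg = background if background is not None else anno.keys()
        return cls(anno, bg)

    def term_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for terms in self.annotations.values():
            for t in terms:
                sizes[t] = sizes.get(t, 0) + 1
        return sizes


def extract_tails(
    std_table: pd.DataFrame,
    fraction: float = DEFAULT_TAIL_FRACTION,
    rank_column: str = "z_level",
) -> list[GeneSetPartition]:
    """Low/high tail gene sets per (taxon, level).

    Genes are ranked within each (taxon, level) by ``rank_column`` (any
    monotone transform of the raw values yields the same sets up to
    boundary ties); k = max(1, floor(fraction * n)).  Boundary ties are
    broken lexicographically by gene id via a stable (value, gene) sort.
    """
    if not (0.0 < fraction < 0.5):
        raise ConfigError(f"tail fraction must lie in (0, 0.5), got {fraction}")
    partitions: list[GeneSetPartition] = []
    for (taxon, level), sub in std_table.groupby(["taxon", "level"], sort=True):
        n = len(sub)
        if n < 1.0 / fraction:
            raise ComputationError(
                f"group ({taxon}, {level}) has n={n} < 1/fraction={1.0 / fraction:.0f}"
            )
        k = max(1, math.floor(fraction * n))
        ordered = sub.sort_values([rank_column, "gene"], kind="stable")
        low = frozenset(ordered["gene"].head(k))
        high = frozenset(ordered["gene"].tail(k))
        partitions.append(
            GeneSetPartition(taxon=str(taxon), level=str(level), k=k, low_set=low, high_set=high)
        )
    return partitions


def venn_counts(
    set_seq: Iterable[str],
    set_expr: Iterable[str],
    set_struct: Iterable[str],
    taxon: str = "",
    tail: str = "",
) -> OverlapSummary:
    """Exclusive region counts of a three-set Venn diagram."""
    a, b, c = set(set_seq), set(set_expr), set(set_struct)
    abc = a & b & c
    ab = (a & b) - abc
    ac = (a & c) - abc
    bc = (b & c) - abc
    return OverlapSummary(
        taxon=taxon,
        tail=tail,
        seq_only=len(a - b - c),
        expr_only=len(b - a - c),
        struct_only=len(c - a - b),
        seq_expr=len(ab),
        seq_struct=len(ac),
        expr_struct=len(bc),
        all_three=len(abc),
    )


def random_overlap_baseline(
    n_genes: int,
    k: int,
    reps: int = 101,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Triple-overlap sizes of randomly sampled gene sets.

    Each replicate draws three independent uniform k-subsets without
    replacement from ``n_genes`` labels and records the size of their
    triple intersection.  The closed-form expectation is ``k**3 / n**2``.
    """
    if k > n_genes:
        raise ConfigError(f"k={k} exceeds n_genes={n_genes}")
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.empty(reps, dtype=int)
    labels = np.arange(n_genes)
    for r in range(reps):
        s1 = rng.choice(labels, size=k, replace=False)
        s2 = rng.choice(labels, size=k, replace=False)
        s3 = rng.choice(labels, size=k, replace=False)
        counts[r] = len(set(s1.tolist()) & set(s2.tolist()) & set(s3.tolist()))
    return {
        "counts": counts,
        "median": float(np.median(counts)),
        "mean": float(counts.mean()),
        "expected": k**3 / n_genes**2,
    }


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ComputationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(study_set: Iterable[str], annotation: AnnotationMap) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in a study set.

    For a term annotating K of the M background genes, with k of the n
    study genes, p = P(X >= k) under the hypergeometric null.  Terms with
    zero study hits are reported with p = 1.  q-values are
    Benjamini-Hochberg adjusted across all terms.  Rows are sorted by
    (p, term).
    """
    study = set(map(str, study_set))
    outside = study - annotation.background
    if outside:
        raise ComputationError(
            f"{len(outside)} study genes outside the background, e.g. {sorted(outside)[:3]}"
        )
    m = len(annotation.background)
    n = len(study)
    term_sizes = annotation.term_sizes()
    study_hits: dict[str, int] = {t: 0 for t in term_sizes}
    for gene in study:
        for t in annotation.annotations.get(gene, ()):  # genes may lack annotations
            study_hits[t] += 1

    terms = sorted(term_sizes)
    rows = []
    for term in terms:
        big_k = term_sizes[term]
        k = study_hits[term]
        p = float(stats.hypergeom.sf(k - 1, m, big_k, n)) if k > 0 else 1.0
        rows.append((term, k, n, big_k, m, min(1.0, p)))
    frame = pd.DataFrame(
        rows, columns=["term", "study_hits", "study_size", "background_hits", "background_size", "p"]
    )
    frame["q"] = benjamini_hochberg(frame["p"].to_numpy()) if len(frame) else []
    return frame.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
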