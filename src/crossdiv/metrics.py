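"""Raw divergence metrics for the three molecular levels.

Sequence divergence is the nonsynonymous substitution rate Ka between a
pair of aligned coding sequences, estimated with the Nei-Gojobori (NG86)
counting method: synonymous/nonsynonymous site counting from the standard
genetic code, pathway averaging for codons differing at multiple positions,
and the Jukes-Cantor multiple-hit correction.  The synonymous rate Ks is
produced by the same computation and serves as a crude mutation-rate proxy.
Externally computed maximum-likelihood estimates (PAML codeml) can be used
instead via :func:`crossdiv.io.parse_codeml_pairwise`.

Expression divergence is the Euclidean distance between relativized
log-transformed multi-tissue expression profiles of the two orthologs.

Structural divergence is the percentage difference ``100 - s`` of the
structural similarity score s reported by flexible structural alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, CrossdivError
from .io import CodonAlignment, ExpressionMatrix, StructuralSimilarityTable

LEVELS = ("sequence", "expression", "structure")

_BASES = "TCAG"
_CODON_TABLE: dict[str, str] = {}
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _aa = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"[
                16 * _i + 4 * _j + _k
            ]
            _CODON_TABLE[_b1 + _b2 + _b3] = _aa

STOP_CODONS = frozenset(c for c, aa in _CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in _CODON_TABLE if c not in STOP_CODONS))


def translate_codon(codon: str) -> str:
    """Amino acid (one letter, '*' for stop) of a DNA codon."""
    return _CODON_TABLE[codon]


@dataclass(frozen=True)
class KaKsResult:
    """Site and difference counts plus corrected rates for one ortholog pair.

    ``ka``/``ks`` are None when the Jukes-Cantor logarithm argument is
    nonpositive (saturation), i.e. the estimate is undefined.
    """

    n_sites: float          # nonsynonymous sites N
    s_sites: float          # synonymous sites S
    n_diffs: float          # nonsynonymous differences Nd
    s_diffs: float          # synonymous differences Sd
    n_codons: int           # codons compared after filtering
    pn: float
    ps: float
    ka: float | None
    ks: float | None


def _codon_site_fractions(codon: str) -> float:
    """Synonymous site count of one codon (sum of per-position fractions).

    A position's synonymous fraction is the share of its three possible
    single-nucleotide changes that preserve the amino acid.  Changes to stop
    codons count as nonsynonymous, so the three positions always contribute
    a full site each and N + S = 3 per codon.
    """
    aa = _CODON_TABLE[codon]
    syn = 0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutated = codon[:pos] + alt + codon[pos + 1 :]
            if _CODON_TABLE[mutated] == aa:
                syn += 1
    return syn / 3.0


_SYN_SITES = {c: _codon_site_fractions(c) for c in SENSE_CODONS}


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous step counts over substitution paths.

    All orderings of the differing positions are enumerated; orderings that
    pass through a stop codon are excluded and the remainder weighted
    equally.  If every ordering is blocked by a stop, all orderings are used
    (the conventional fallback for the rare fully-blocked case).
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_positions):
        current = codon_a
        syn = non = 0
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                hit_stop = True
            if _CODON_TABLE[nxt] == _CODON_TABLE[current]:
                syn += 1
            else:
                non += 1
            current = nxt
        (blocked if hit_stop else valid).append((syn, non))
    paths = valid if valid else blocked
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    return s, n


def nei_gojobori(alignment: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks estimate for one pairwise codon alignment.

    Codon columns containing a gap or ambiguity character in either
    sequence, or a stop codon, are removed pairwise.  Site counts are
    averaged across the two sequences; multi-hit codons are resolved by
    equal-weight pathway averaging avoiding stop intermediates; proportions
    are corrected with the Jukes-Cantor formula
    ``K = -(3/4) ln(1 - (4/3) p)``.
    """
    kept: list[tuple[str, str]] = []
    for ca, cb in alignment.codons():
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        kept.append((ca, cb))
    if not kept:
        raise ComputationError(
            f"no comparable codons between {alignment.id_a} and {alignment.id_b}"
        )

    s_sites = sum((_SYN_SITES[ca] + _SYN_SITES[cb]) / 2.0 for ca, cb in kept)
    n_sites = 3.0 * len(kept) - s_sites
    s_diffs = n_diffs = 0.0
    for ca, cb in kept:
        ds, dn = _pathway_counts(ca, cb)
        s_diffs += ds
        n_diffs += dn

    ps = s_diffs / s_sites if s_sites > 0 else 0.0
    pn = n_diffs / n_sites if n_sites > 0 else 0.0
    return KaKsResult(
        n_sites=n_sites,
        s_sites=s_sites,
        n_diffs=n_diffs,
        s_diffs=s_diffs,
        n_codons=len(kept),
        pn=pn,
        ps=ps,
        ka=_jukes_cantor(pn),
        ks=_jukes_cantor(ps),
    )


def _jukes_cantor(p: float) -> float | None:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    if arg == 1.0:
        return 0.0
    return -0.75 * math.log(arg)


# ---------------------------------------------------------------------------
# expression divergence
# ---------------------------------------------------------------------------

def expression_profile_divergence(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    tissue_map: Mapping[str, str],
) -> dict[str, float]:
    """Euclidean distance between relativized expression profiles.

    ``tissue_map`` pairs each tissue of species a with its counterpart in
    species b.  Genes with TPM < 1 in all mapped tissues of either species
    are removed; surviving values are transformed log2(TPM + 1) and each
    gene's profile divided by its sum across tissues, so profiles compare
    shape rather than magnitude.  Distances are computed over the matched
    tissue order.
    """
    if not tissue_map:
        raise ComputationError("empty tissue map")
    tissues_a = list(tissue_map.keys())
    tissues_b = [tissue_map[t] for t in tissues_a]
    for t in tissues_a:
        if t not in matrix_a.tpm.columns:
            raise ComputationError(f"tissue {t!r} absent from first matrix")
    for t in tissues_b:
        if t not in matrix_b.tpm.columns:
            raise ComputationError(f"tissue {t!r} absent from second matrix")

    shared = [g for g in matrix_a.gene_ids if g in set(matrix_b.gene_ids)]
    if not shared:
        raise ComputationError("matrices share no gene ids")

    a = matrix_a.tpm.loc[shared, tissues_a].to_numpy(dtype=float)
    b = matrix_b.tpm.loc[shared, tissues_b].to_numpy(dtype=float)

    # low-expression filter, applied per species: drop if TPM < 1 everywhere
    keep = (a >= 1.0).any(axis=1) & (b >= 1.0).any(axis=1)

    la = np.log2(a + 1.0)
    lb = np.log2(b + 1.0)
    sum_a = la.sum(axis=1)
    sum_b = lb.sum(axis=1)
    keep &= (sum_a > 0) & (sum_b > 0)

    out: dict[str, float] = {}
    for idx, gene in enumerate(shared):
        if not keep[idx]:
            continue
        pa = la[idx] / sum_a[idx]
        pb = lb[idx] / sum_b[idx]
        out[gene] = float(np.linalg.norm(pa - pb))
    return out


# ---------------------------------------------------------------------------
# structural divergence
# ---------------------------------------------------------------------------

def structural_divergence(similarity: StructuralSimilarityTable) -> dict[str, float]:
    """Percentage difference ``100 - s`` per gene."""
    return {gene: 100.0 - similarity[gene] for gene in similarity}


# ---------------------------------------------------------------------------
# joint table assembly
# ---------------------------------------------------------------------------

def assemble_raw_table(
    taxon: str,
    sequence_divs: Mapping[str, float | None],
    expression_divs: Mapping[str, float],
    structure_divs: Mapping[str, float],
) -> pd.DataFrame:
    """Join the three per-gene divergence mappings into one long table.

    Genes must be present at all three levels (missing data removed);
    genes with an undefined sequence estimate are dropped.  Returns a frame
    with columns ``gene, taxon, level, raw`` sorted by gene id.
    """
    seq_ok = {
        g: v
        for g, v in sequence_divs.items()
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    }
    common = sorted(set(seq_ok) & set(expression_divs) & set(structure_divs))
    if not common:
        raise ComputationError(
            "no genes shared across levels "
            f"(sequence: {len(seq_ok)}, expression: {len(expression_divs)}, "
            f"structure: {len(structure_divs)})"
        )
    rows = []
    for gene in common:
        rows.append((gene, taxon, "sequence", float(seq_ok[gene])))
        rows.append((gene, taxon, "expression", float(expression_divs[gene])))
        rows.append((gene, taxon, "structure", float(structure_divs[gene])))
    frame = pd.DataFrame(rows, columns=["gene", "taxon", "level", "raw"])
    if (frame["raw"] < 0).any():
        raise CrossdivError("negative raw divergence value")
    return frame
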