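"""Synthetic data with the statistical structure the analysis assumes.

The generator produces everything the pipeline consumes, at two levels of
abstraction:

* per-taxon raw divergence tables drawn from a Gaussian copula with
  zero-inflated gamma marginals per (taxon, level);
* low-level inputs — codon alignment pairs with controlled synonymous and
  nonsynonymous substitution loads, paired multi-tissue TPM matrices, and
  structural similarity scores — so each metric stage can be exercised
  end to end without external downloads.

Marginal model.  Raw divergence at each (taxon, level) is zero with
probability ``zero_inflation`` (saturation: identical proteins have
Ka = 0, identical structures score s = 100) and otherwise gamma
distributed.  The copula couples the three levels of a gene with small
positive correlations (default off-diagonal 0.30).

The default parameter table encodes the qualitative cross-taxa and
cross-level orderings the standardization stage is expected to reveal:
saturation mass increases from sequence to expression to structure within
every taxon (making the level-specific z medians rise in that order), the
Drosophila row carries the most saturation overall and the primates row
the least (placing Drosophila's taxon-specific z medians highest at every
level), and the primates sequence scale is reduced (placing primates
lowest at the sequence level).  Scale parameters are matched to the
saturation masses so that group medians stay aligned; the numerical
values were calibrated by simulation at design time.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .io import CodonAlignment, ExpressionMatrix, StructuralSimilarityTable
from .metrics import LEVELS, SENSE_CODONS, STOP_CODONS, _CODON_TABLE

DEFAULT_TAXA = ("Drosophila", "rodents", "primates", "Arabidopsis")

# per (taxon, level) defaults; levels ordered (sequence, expression, structure)
_DEFAULT_SHAPE = {t: (1.35, 1.2, 1.1) for t in DEFAULT_TAXA}
_DEFAULT_SCALE = {
    "Drosophila": (0.1016, 0.3941, 1.2485),
    "rodents": (0.08, 0.2029, 0.5177),
    "primates": (0.072, 0.1885, 0.302),
    "Arabidopsis": (0.08, 0.2029, 0.5177),
}
_DEFAULT_ZERO_INFLATION = {
    "Drosophila": (0.16, 0.34, 0.42),
    "rodents": (0.0, 0.15, 0.34),
    "primates": (0.0, 0.11, 0.18),
    "Arabidopsis": (0.0, 0.15, 0.34),
}
_DEFAULT_CORR = 0.30


def _default_corr_matrix() -> np.ndarray:
    m = np.full((3, 3), _DEFAULT_CORR)
    np.fill_diagonal(m, 1.0)
    return m


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the divergence-table generator.

    ``marginal_shape``, ``marginal_scale`` and ``zero_inflation`` map each
    taxon to its (sequence, expression, structure) triple; ``copula_corr``
    maps each taxon to a 3x3 correlation matrix over the levels.
    """

    taxa: tuple[str, ...] = DEFAULT_TAXA
    genes_per_taxon: int = 2000
    marginal_shape: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SHAPE)
    )
    marginal_scale: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SCALE)
    )
    zero_inflation: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_ZERO_INFLATION)
    )
    copula_corr: Mapping[str, np.ndarray] = field(
        default_factory=lambda: {t: _default_corr_matrix() for t in DEFAULT_TAXA}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.taxa) == 0:
            raise ConfigError("at least one taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise ConfigError("duplicate taxon labels")
        if self.genes_per_taxon < 10:
            raise ConfigError("genes_per_taxon must be >= 10")
        if self.seed < 0:
            raise ConfigError("seed must be nonnegative")
        for t in self.taxa:
            for table, name in (
                (self.marginal_shape, "marginal_shape"),
                (self.marginal_scale, "marginal_scale"),
                (self.zero_inflation, "zero_inflation"),
            ):
                if t not in table:
                    raise ConfigError(f"{name} missing taxon {t!r}")
                triple = table[t]
                if len(triple) != 3:
                    raise ConfigError(f"{name}[{t!r}] must have 3 entries (one per level)")
            if any(v <= 0 for v in self.marginal_shape[t]):
                raise ConfigError(f"marginal_shape[{t!r}] must be strictly positive")
            if any(v <= 0 for v in self.marginal_scale[t]):
                raise ConfigError(f"marginal_scale[{t!r}] must be strictly positive")
            if any(not (0.0 <= v < 0.5) for v in self.zero_inflation[t]):
                raise ConfigError(f"zero_inflation[{t!r}] must lie in [0, 0.5)")
            if t not in self.copula_corr:
                raise ConfigError(f"copula_corr missing taxon {t!r}")
            corr = np.asarray(self.copula_corr[t], dtype=float)
            if corr.shape != (3, 3):
                raise ConfigError(f"copula_corr[{t!r}] must be 3x3")
            if not np.allclose(corr, corr.T, atol=1e-12):
                raise ConfigError(f"copula_corr[{t!r}] is not symmetric")
            if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
                raise ConfigError(f"copula_corr[{t!r}] diagonal must be 1")
            eigmin = float(np.linalg.eigvalsh(corr).min())
            if eigmin < -1e-10:
                raise ConfigError(
                    f"copula_corr[{t!r}] is not positive semidefinite (min eigenvalue {eigmin:.3g})"
                )

    @classmethod
    def from_toml(cls, path) -> "SyntheticConfig":
        """Load a config from a TOML file (see the repository's demo config).

        Accepts either a bare synthetic config or a full run config whose
        ``[synthetic]`` table holds the generator parameters.
        """
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "synthetic" in data:
            data = data["synthetic"]
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        kwargs: dict = {}
        if "taxa" in data:
            kwargs["taxa"] = tuple(data["taxa"])
        for key in ("genes_per_taxon", "seed"):
            if key in data:
                kwargs[key] = int(data[key])
        taxa = kwargs.get("taxa", DEFAULT_TAXA)
        for key in ("marginal_shape", "marginal_scale", "zero_inflation"):
            if key in data:
                kwargs[key] = {t: tuple(map(float, data[key][t])) for t in data[key]}
        if "copula_corr" in data:
            raw = data["copula_corr"]
            if isinstance(raw, (int, float)):
                m = np.full((3, 3), float(raw))
                np.fill_diagonal(m, 1.0)
                kwargs["copula_corr"] = {t: m for t in taxa}
            else:
                kwargs["copula_corr"] = {t: np.asarray(raw[t], dtype=float) for t in raw}
        elif set(taxa) != set(DEFAULT_TAXA):
            # the default correlation is taxon-independent; fill it for custom taxa
            kwargs["copula_corr"] = {t: _default_corr_matrix() for t in taxa}
        return cls(**kwargs)


def generate_divergence_tables(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Draw one long raw-divergence table per taxon.

    Each gene receives values at all three levels via the Gaussian copula:
    a 3-dimensional normal draw with the taxon's correlation matrix is
    mapped through the standard normal CDF and inverted through the
    zero-inflated gamma marginal of each (taxon, level).  Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tables: dict[str, pd.DataFrame] = {}
    n = config.genes_per_taxon
    for taxon in config.taxa:
        corr = np.asarray(config.copula_corr[taxon], dtype=float)
        # nearest-PSD guard for numerically semi-definite inputs
        w, v = np.linalg.eigh(corr)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        normals = rng.standard_normal((n, 3)) @ chol.T
        u = stats.norm.cdf(normals)
        genes = [f"{taxon}_g{i:05d}" for i in range(1, n + 1)]
        rows = []
        for j, level in enumerate(LEVELS):
            pi0 = config.zero_inflation[taxon][j]
            shape = config.marginal_shape[taxon][j]
            scale = config.marginal_scale[taxon][j]
            uj = u[:, j]
            vals = np.zeros(n)
            cont = uj >= pi0
            if pi0 < 1.0:
                rescaled = (uj[cont] - pi0) / (1.0 - pi0)
                # clip away the endpoints to keep ppf finite
                rescaled = np.clip(rescaled, 1e-12, 1.0 - 1e-12)
                vals[cont] = stats.gamma.ppf(rescaled, shape, scale=scale)
            for i, gene in enumerate(genes):
                rows.append((gene, taxon, level, float(vals[i])))
        frame = pd.DataFrame(rows, columns=["gene", "taxon", "level", "raw"])
        frame = frame.sort_values(["gene", "level"], kind="stable").reset_index(drop=True)
        tables[taxon] = frame
    return tables


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------

def _codon_options() -> dict[str, tuple[tuple[str, ...], tuple[str, ...]]]:
    """Per codon: the non-stop single-nucleotide neighbours, split into
    (synonymous, nonsynonymous) target codons."""
    table: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    for codon in SENSE_CODONS:
        aa = _CODON_TABLE[codon]
        syn, non = [], []
        for pos in range(3):
            for alt in "TCAG":
                if alt == codon[pos]:
                    continue
                mutated = codon[:pos] + alt + codon[pos + 1 :]
                if mutated in STOP_CODONS:
                    continue
                (syn if _CODON_TABLE[mutated] == aa else non).append(mutated)
        table[codon] = (tuple(syn), tuple(non))
    return table


_CODON_OPTIONS = _codon_options()


def generate_codon_alignment(
    n_codons: int,
    t_syn: float,
    t_non: float,
    seed: int | np.random.Generator = 0,
) -> CodonAlignment:
    """Simulate an ancestral/derived coding-sequence pair.

    The ancestral sequence is drawn uniformly over sense codons.  Poisson
    numbers of synonymous and nonsynonymous events — with means
    ``t_syn * S`` and ``t_non * N`` for the ancestor's NG86 site counts S
    and N — are applied in random interleaved order; each event picks
    uniformly among the currently available single-nucleotide changes of
    its class, rejecting changes that would create a stop codon.  Both
    sequences are stop-free with length ``3 * n_codons``.
    """
    if n_codons < 1:
        raise ConfigError("n_codons must be >= 1")
    if t_syn < 0 or t_non < 0:
        raise ConfigError("substitution loads must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ancestor = list(rng.choice(SENSE_CODONS, size=n_codons))
    from .metrics import _SYN_SITES  # local import to avoid cycle at module load

    s_sites = sum(_SYN_SITES[c] for c in ancestor)
    n_sites = 3.0 * n_codons - s_sites

    n_syn_events = int(rng.poisson(t_syn * s_sites))
    n_non_events = int(rng.poisson(t_non * n_sites))
    events = ["syn"] * n_syn_events + ["non"] * n_non_events
    rng.shuffle(events)

    derived = list(ancestor)
    kind_idx = {"syn": 0, "non": 1}
    counts = np.array(
        [[len(_CODON_OPTIONS[c][0]), len(_CODON_OPTIONS[c][1])] for c in derived], dtype=float
    )
    for kind in events:
        j = kind_idx[kind]
        total = counts[:, j].sum()
        if total == 0:  # unreachable in practice for nonzero-length sequences
            continue
        # pick a codon weighted by its number of available changes, then a change
        cum = np.cumsum(counts[:, j])
        ci = int(np.searchsorted(cum, rng.uniform(0.0, total), side="right"))
        choices = _CODON_OPTIONS[derived[ci]][j]
        derived[ci] = choices[int(rng.integers(len(choices)))]
        counts[ci] = (len(_CODON_OPTIONS[derived[ci]][0]), len(_CODON_OPTIONS[derived[ci]][1]))

    return CodonAlignment(
        id_a="ancestor", id_b="derived", seq_a="".join(ancestor), seq_b="".join(derived)
    )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def generate_expression_pair(
    n_genes: int,
    n_tissues: int,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
    log_mean: float = 2.0,
    log_sd: float = 1.5,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Simulate matched TPM matrices for two species.

    Species 1 TPM is log-normal per (gene, tissue); species 2 log-TPM is
    species 1 log-TPM plus Gaussian noise with standard deviation
    ``noise_sd``, exponentiated.  Both matrices share gene ids and carry
    matched tissue labels (``tissue_k`` vs ``tissue_k_b``).
    """
    if n_genes < 1 or n_tissues < 1:
        raise ConfigError("n_genes and n_tissues must be >= 1")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    tissues_a = [f"tissue_{j}" for j in range(1, n_tissues + 1)]
    tissues_b = [f"{t}_b" for t in tissues_a]

    log_a = rng.normal(log_mean, log_sd, size=(n_genes, n_tissues))
    log_b = log_a + rng.normal(0.0, noise_sd, size=(n_genes, n_tissues)) if noise_sd > 0 else log_a.copy()

    a = ExpressionMatrix(pd.DataFrame(np.exp(log_a), index=genes, columns=tissues_a))
    b = ExpressionMatrix(pd.DataFrame(np.exp(log_b), index=genes, columns=tissues_b))
    return a, b


def default_tissue_map(matrix_a: ExpressionMatrix, matrix_b: ExpressionMatrix) -> dict[str, str]:
    """Positional tissue pairing for matrices produced by the generator."""
    return dict(zip(matrix_a.tissue_ids, matrix_b.tissue_ids))


# ---------------------------------------------------------------------------
# structural similarities
# ---------------------------------------------------------------------------

def generate_structural_similarities(
    n_genes: int,
    mean_divergence: float,
    sd: float,
    seed: int | np.random.Generator = 0,
) -> StructuralSimilarityTable:
    """Simulate similarity scores ``s = 100 - d``.

    Structural differences d are drawn from a normal distribution with the
    stated mean and sd truncated to [0, 100], so all s lie in [0, 100].
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    if not (0.0 <= mean_divergence <= 100.0):
        raise ConfigError("mean_divergence must lie in [0, 100]")
    if sd < 0:
        raise ConfigError("sd must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    if sd == 0:
        d = np.full(n_genes, mean_divergence)
    else:
        a = (0.0 - mean_divergence) / sd
        b = (100.0 - mean_divergence) / sd
        d = stats.truncnorm.rvs(a, b, loc=mean_divergence, scale=sd, size=n_genes, random_state=rng)
    return StructuralSimilarityTable({g: 100.0 - float(x) for g, x in zip(genes, d)})
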