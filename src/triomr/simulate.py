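"""Synthetic mother-father-child trio cohorts.

Generates biallelic genotype dosages for parental couples, pairs spouses by a
latent assortment score, transmits alleles Mendelianly to one child per
couple, and builds phenotypes with dynastic (parent-phenotype -> child
outcome), direct-genetic and per-variant pleiotropic components.

The generative model
--------------------
Parental dosages are drawn Binomial(2, f_j) per person and locus.  Spouses
are matched on

    a = phi * z(g) + (1 - phi) * v,        v ~ N(0, 1)

where z(g) is the standardized mean dosage across loci and phi in [0, 1]
controls the strength of genotypic assortment; matching is rank-order
(sort both pools on a, pair rank to rank).  Each child receives one allele
drawn uniformly from each parent's pair at every locus.  Phenotypes:

    x_p = g_p @ w + eps_p                  (parental exposure, p in {m, f})
    y   = b_m x_m + b_f x_f + d * (g_c @ w) + g_c @ alpha + eps_y

with per-variant pleiotropy alpha_j ~ N(mu_a, sd_a^2).  Setting d = 0 and
alpha = 0 with a single locus reproduces the classic one-SNP dynastic-effect
simulation (parental exposure = genotype + standard normal noise, child
outcome = sum of parental phenotypes + standard normal noise).

All randomness flows from a single root seed through named per-stage child
streams, so e.g. adding variants does not perturb the phenotype noise.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TrioCohort",
    "simulate_parental_genotypes",
    "assort_couples",
    "transmit_genotypes",
    "generate_phenotypes",
    "simulate_trio_cohort",
]

# Stage names mapped to stable offsets of the root SeedSequence so that each
# stage gets an independent, reproducible stream.
_STAGES = ("parental_genotypes", "assortment", "transmission", "pleiotropy",
           "exposure_noise", "outcome_noise")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the trio-cohort generative model.

    Parameters
    ----------
    n_couples
        Number of mother-father pairs (one child each).
    n_snps
        Number of independent biallelic loci.
    allele_freqs
        Effect-allele frequency, scalar or length ``n_snps``; must lie
        strictly inside (0, 1).
    assortment_phi
        Weight of the standardized genotype in the spousal matching score;
        0 = random mating, 1 = matching on genotype alone.
    dynastic_effect_mother, dynastic_effect_father
        Effect of each parent's exposure phenotype on the child outcome.
    direct_effect
        Effect of the child's own genotypic score (g_c @ w) on the outcome.
    pleiotropy_mean, pleiotropy_sd
        Moments of the per-variant pleiotropic effect on the child outcome
        acting through the child's dosage; (0, 0) disables pleiotropy.
    exposure_effect
        Per-allele effect of genotype on the parental exposure, scalar or
        length ``n_snps``.
    noise_sd_exposure, noise_sd_outcome
        Standard deviations of the exposure and outcome noise terms.
    seed
        Root seed; identical config + seed gives a bit-identical cohort.
    """

    n_couples: int
    n_snps: int = 1
    allele_freqs: float | Sequence[float] = 0.5
    assortment_phi: float = 0.0
    dynastic_effect_mother: float = 1.0
    dynastic_effect_father: float = 1.0
    direct_effect: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    exposure_effect: float | Sequence[float] = 1.0
    noise_sd_exposure: float = 1.0
    noise_sd_outcome: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_couples < 0 or self.n_snps < 0:
            raise ConfigError("n_couples and n_snps must be nonnegative")
        if not 0.0 <= self.assortment_phi <= 1.0:
            raise ConfigError(
                f"assortment_phi must lie in [0, 1], got {self.assortment_phi}")
        f = self.freq_vector()
        if not np.all(np.isfinite(f)) or np.any(f <= 0.0) or np.any(f >= 1.0):
            raise ConfigError("allele frequencies must be finite and strictly "
                              "inside (0, 1)")
        if self.pleiotropy_sd < 0:
            raise ConfigError("pleiotropy_sd must be >= 0")
        if self.noise_sd_exposure <= 0 or self.noise_sd_outcome <= 0:
            raise ConfigError("noise standard deviations must be > 0")

    def freq_vector(self) -> np.ndarray:
        """Allele frequencies broadcast to shape (n_snps,)."""
        f = np.asarray(self.allele_freqs, dtype=float)
        if f.ndim == 0:
            f = np.full(self.n_snps, float(f))
        if f.shape != (self.n_snps,):
            raise ConfigError(
                f"allele_freqs has shape {f.shape}, expected ({self.n_snps},)")
        return f

    def exposure_weights(self) -> np.ndarray:
        """Genotype -> exposure weights broadcast to shape (n_snps,)."""
        w = np.asarray(self.exposure_effect, dtype=float)
        if w.ndim == 0:
            w = np.full(self.n_snps, float(w))
        if w.shape != (self.n_snps,):
            raise ConfigError(
                f"exposure_effect has shape {w.shape}, expected "
                f"({self.n_snps},)")
        return w

    def rng(self, stage: str) -> np.random.Generator:
        """Independent generator for a named simulation stage."""
        if stage not in _STAGES:
            raise KeyError(f"unknown stage {stage!r}")
        root = np.random.SeedSequence(self.seed)
        return np.random.default_rng(root.spawn(len(_STAGES))[_STAGES.index(stage)])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("allele_freqs", "exposure_effect"):
            if isinstance(d[key], np.ndarray):
                d[key] = d[key].tolist()
        return d


@dataclass
class TrioCohort:
    """Aligned genotypes, phenotypes and covariates for complete trios.

    All matrices share the family index: row i of every array belongs to
    family ``family_id[i]``.
    """

    family_id: np.ndarray
    variant_ids: list[str]
    dosage_mother: np.ndarray
    dosage_father: np.ndarray
    dosage_child: np.ndarray
    phenotypes: pd.DataFrame  # columns: exposure_mother, exposure_father, outcome_child
    covariates: np.ndarray | None = None
    config: SimConfig | None = None

    @property
    def n_families(self) -> int:
        return len(self.family_id)

    @property
    def n_snps(self) -> int:
        return len(self.variant_ids)

    def validate_transmission(self) -> None:
        """Raise if any child dosage is Mendelianly impossible.

        A child allele count at a locus must be expressible as one allele
        from each parent: c = c_m + c_f with c_p in the set a parent of
        dosage d can transmit ({0} for d=0, {0,1} for d=1, {1} for d=2).
        """
        m, f, c = (np.asarray(a) for a in
                   (self.dosage_mother, self.dosage_father, self.dosage_child))
        lo = (m == 2).astype(int) + (f == 2).astype(int)
        hi = 2 - (m == 0).astype(int) - (f == 0).astype(int)
        bad = (c < lo) | (c > hi)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"Mendelian violation: family {self.family_id[i]}, variant "
                f"{self.variant_ids[j]}: parents ({m[i, j]}, {f[i, j]}) "
                f"child {c[i, j]}")


def simulate_parental_genotypes(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw mother and father dosage matrices, Binomial(2, f_j) per locus.

    Returns two int8 arrays of shape (n_couples, n_snps).  Mothers and
    fathers are unpaired at this stage; see :func:`assort_couples`.
    """
    f = config.freq_vector()
    rng = config.rng("parental_genotypes")
    shape = (config.n_couples, config.n_snps)
    mothers = rng.binomial(2, f, size=shape).astype(np.int8)
    fathers = rng.binomial(2, f, size=shape).astype(np.int8)
    return mothers, fathers


def _latent_scores(dosages: np.ndarray, phi: float,
                   rng: np.random.Generator) -> np.ndarray:
    """phi * standardized mean dosage + (1 - phi) * standard normal noise."""
    g = np.asarray(dosages, dtype=float).mean(axis=1)
    sd = g.std()
    z = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)
    v = rng.standard_normal(len(g))
    return phi * z + (1.0 - phi) * v


def assort_couples(mothers: np.ndarray, fathers: np.ndarray, phi: float,
                   seed_or_rng) -> np.ndarray:
    """Pair spouses by rank of the latent assortment score.

    Both pools are sorted on their score ``a = phi*z(g) + (1-phi)*v`` and
    matched rank to rank.  Returns an integer permutation ``p`` such that
    father ``p[i]`` is the spouse of mother ``i``.
    """
    if not 0.0 <= phi <= 1.0:
        raise ConfigError(f"phi must lie in [0, 1], got {phi}")
    if len(mothers) != len(fathers):
        raise ValueError("mother and father pools must be the same size")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    a_m = _latent_scores(mothers, phi, rng)
    a_f = _latent_scores(fathers, phi, rng)
    # rank r mother gets rank r father
    order_m = np.argsort(a_m, kind="stable")
    order_f = np.argsort(a_f, kind="stable")
    pairing = np.empty(len(mothers), dtype=np.int64)
    pairing[order_m] = order_f
    return pairing


def transmit_genotypes(mothers: np.ndarray, fathers: np.ndarray,
                       pairing: np.ndarray, seed_or_rng) -> np.ndarray:
    """Draw one child per couple by uniform allele transmission.

    At each locus the child receives one allele drawn uniformly from each
    parent's two alleles, so a parent of dosage d transmits the effect
    allele with probability d/2 and E[child | parents] = (d_m + d_f)/2.
    """
    mothers = np.asarray(mothers)
    fathers = np.asarray(fathers)
    pairing = np.asarray(pairing)
    if sorted(pairing.tolist()) != list(range(len(mothers))):
        raise ValueError("pairing must be a permutation of the father pool")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    paired_f = fathers[pairing]
    u_m = rng.random(mothers.shape)
    u_f = rng.random(mothers.shape)
    child = (u_m < mothers / 2.0).astype(np.int8) + \
            (u_f < paired_f / 2.0).astype(np.int8)
    return child


def generate_phenotypes(mothers: np.ndarray, fathers: np.ndarray,
                        children: np.ndarray, config: SimConfig) -> pd.DataFrame:
    """Fill exposure and outcome phenotypes for aligned trio matrices.

    ``mothers``/``fathers`` must already be couple-aligned (same row = same
    family).  Returns a DataFrame with columns ``exposure_mother``,
    ``exposure_father`` and ``outcome_child``.
    """
    for name, arr in (("mothers", mothers), ("fathers", fathers),
                      ("children", children)):
        if arr is None:
            raise ValueError(f"{name} genotypes missing")
    n = len(mothers)
    w = config.exposure_weights()
    rng_a = config.rng("pleiotropy")
    rng_x = config.rng("exposure_noise")
    rng_y = config.rng("outcome_noise")

    alpha = rng_a.normal(config.pleiotropy_mean, config.pleiotropy_sd,
                         size=config.n_snps) if config.pleiotropy_sd > 0 \
        else np.full(config.n_snps, config.pleiotropy_mean)

    gm = np.asarray(mothers, dtype=float)
    gf = np.asarray(fathers, dtype=float)
    gc = np.asarray(children, dtype=float)

    x_m = gm @ w + rng_x.normal(0.0, config.noise_sd_exposure, n)
    x_f = gf @ w + rng_x.normal(0.0, config.noise_sd_exposure, n)
    y = (config.dynastic_effect_mother * x_m
         + config.dynastic_effect_father * x_f
         + config.direct_effect * (gc @ w)
         + gc @ alpha
         + rng_y.normal(0.0, config.noise_sd_outcome, n))
    return pd.DataFrame({"exposure_mother": x_m, "exposure_father": x_f,
                         "outcome_child": y})


def simulate_trio_cohort(config: SimConfig) -> TrioCohort:
    """Run the full pipeline: draw parents, assort, transmit, phenotype.

    Deterministic given ``config.seed``; the returned cohort carries the
    config as its provenance record.
    """
    mothers, fathers = simulate_parental_genotypes(config)
    pairing = assort_couples(mothers, fathers, config.assortment_phi,
                             config.rng("assortment"))
    fathers = fathers[pairing]
    children = transmit_genotypes(mothers, fathers, np.arange(config.n_couples),
                                  config.rng("transmission"))
    phenotypes = generate_phenotypes(mothers, fathers, children, config)
    family_id = np.array([f"F{i:06d}" for i in range(config.n_couples)])
    phenotypes.index = pd.Index(family_id, name="family_id")
    variant_ids = [f"snp{j + 1}" for j in range(config.n_snps)]
    return TrioCohort(family_id=family_id, variant_ids=variant_ids,
                      dosage_mother=mothers, dosage_father=fathers,
                      dosage_child=children, phenotypes=phenotypes,
                      config=config)
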