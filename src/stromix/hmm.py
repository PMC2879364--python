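"""Decoding machinery: transitions, emissions, Viterbi, segmentation.

Transitions depend on the genomic distance d between adjacent SNPs through
an exponential leave-probability: a state i is left with probability
rho_i(d) = (1 - pi_i) * (1 - exp(-d / L_i)), and given a change the next
state is drawn from the stationary distribution restricted to j != i
(independence of the destination from the origin). As d -> 0 the matrix
tends to the identity; as d -> inf every row tends to the stationary vector
and the mean length of a state-i region tends to L_i.

LRR emissions are a Gaussian/uniform mixture (the uniform absorbs assay
fluctuations with weight pi0). BAF emissions mix the uniform with four
Gaussians, one per genotype class, weighted by the germline class priors;
the Gaussians are *censored* at 0 and 1, so mass that would fall outside
[0,1] appears as point masses at the boundaries — exactly the spikes the
assay produces for homozygous genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import EmissionTable, HMMModel
from .states import state_cn_ai

__all__ = [
    "transition_matrix",
    "lrr_emission",
    "baf_emission",
    "log_emission_matrix",
    "viterbi_decode",
    "viterbi_path",
    "segment_path",
    "call_genotype",
    "CNVRegion",
    "NO_GENOTYPE",
]

#: density floor applied before taking logs, to keep the decoder finite
DENSITY_FLOOR = 1e-300

NO_GENOTYPE = "-"


def transition_matrix(d: float, model: HMMModel) -> np.ndarray:
    """Row-stochastic transition matrix for an inter-SNP distance ``d`` (bp)."""
    if d <= 0:
        raise ValueError(f"inter-SNP distance must be positive: {d}")
    pi = model.stationary()
    length = model.mean_lengths()
    rho = (1.0 - pi) * -np.expm1(-d / length)   # leave probability per state
    a = rho[:, None] * (pi[None, :] / (1.0 - pi)[:, None])
    np.fill_diagonal(a, 1.0 - rho)
    return a


# ---------------------------------------------------------------------------
# emissions

def _uniform_pdf(x: np.ndarray | float, support: tuple[float, float]):
    lo, hi = support
    inside = (np.asarray(x) >= lo) & (np.asarray(x) <= hi)
    return np.where(inside, 1.0 / (hi - lo), 0.0)


def lrr_emission(r: float, state_idx: int, model: HMMModel,
                 emissions: EmissionTable | None = None) -> float:
    """Mixture density of an LRR observation under one state.

    States sharing a copy number share this distribution (their default
    means and SDs are equal), so LRR separates copy numbers while BAF
    separates states within a copy number.
    """
    em = model.emissions() if emissions is None else emissions
    mu = em.lrr_mean[state_idx]
    sd = em.lrr_sd[state_idx]
    pi0 = model.outlier_weight
    return float(pi0 * _uniform_pdf(r, model.lrr_uniform)
                 + (1.0 - pi0) * norm.pdf(r, mu, sd))


def _censored_class_values(b: np.ndarray, means: np.ndarray,
                           sds: np.ndarray) -> np.ndarray:
    """Censored-Gaussian value of each genotype class at each BAF.

    Interior points get the pdf; b == 0 and b == 1 get the censored point
    masses Phi((0-mu)/sd) and 1 - Phi((1-mu)/sd). ``b`` has shape (N,),
    ``means``/``sds`` any shape broadcastable to (N, ...).
    """
    b = np.asarray(b, dtype=float)
    bb = b.reshape(b.shape + (1,) * (means.ndim))
    vals = norm.pdf(bb, means, sds)
    at_zero = b <= 0.0
    at_one = b >= 1.0
    if at_zero.any():
        vals[at_zero] = norm.cdf(0.0, means, sds)
    if at_one.any():
        vals[at_one] = norm.sf(1.0, means, sds)
    return vals


def baf_emission(b: float, state_idx: int, p_b: float, model: HMMModel,
                 emissions: EmissionTable | None = None) -> float:
    """Mixture value of a BAF observation under one state.

    Returns a density for 0 < b < 1 and a probability (boundary point mass)
    at b = 0 or 1; integral of the density plus the two masses is 1.
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"BAF must be in [0,1]: {b}")
    em = model.emissions() if emissions is None else emissions
    from .states import genotype_class_priors
    w = np.array(genotype_class_priors(p_b))
    vals = _censored_class_values(np.array([b]), em.baf_means[state_idx],
                                  em.baf_sds[state_idx])[0]
    pi0 = model.outlier_weight
    boundary = b <= 0.0 or b >= 1.0
    unif = 0.0 if boundary else float(_uniform_pdf(b, model.baf_uniform))
    return float(pi0 * unif + (1.0 - pi0) * (w * vals).sum())


def log_emission_matrix(baf: np.ndarray, lrr: np.ndarray, p_b: np.ndarray,
                        model: HMMModel,
                        emissions: EmissionTable | None = None) -> np.ndarray:
    """(n_snps, n_states) matrix of joint log emissions.

    LRR and BAF are treated as independent given the state, so the joint
    log emission is the sum of the two log mixture values.
    """
    em = model.emissions() if emissions is None else emissions
    baf = np.asarray(baf, dtype=float)
    lrr = np.asarray(lrr, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    pi0 = model.outlier_weight

    lrr_dens = (pi0 * _uniform_pdf(lrr, model.lrr_uniform)[:, None]
                + (1.0 - pi0) * norm.pdf(lrr[:, None], em.lrr_mean, em.lrr_sd))

    # class weights per SNP: ((1-p)^2, p^2, p(1-p), p(1-p))
    q = 1.0 - p_b
    w = np.stack([q * q, p_b * p_b, p_b * q, p_b * q], axis=1)   # (N, 4)
    vals = _censored_class_values(baf, em.baf_means, em.baf_sds)  # (N, S, 4)
    boundary = (baf <= 0.0) | (baf >= 1.0)
    unif_b = np.where(boundary, 0.0, _uniform_pdf(baf, model.baf_uniform))
    baf_dens = (pi0 * unif_b[:, None]
                + (1.0 - pi0) * np.einsum("ng,nsg->ns", w, vals))

    dens = np.maximum(lrr_dens, DENSITY_FLOOR) * np.maximum(baf_dens, DENSITY_FLOOR)
    return np.log(np.maximum(dens, DENSITY_FLOOR))


# ---------------------------------------------------------------------------
# Viterbi

def viterbi_path(log_pi: np.ndarray, log_trans: list[np.ndarray] | np.ndarray,
                 log_emis: np.ndarray) -> np.ndarray:
    """Maximum a-posteriori state path by dynamic programming.

    ``log_trans`` is one (S, S) matrix per step (length n-1), or a single
    matrix reused for every step. Ties are broken toward the lower state
    index (lower copy number in canonical order), making decoding
    deterministic.
    """
    n, s = log_emis.shape
    if n == 0:
        raise ValueError("empty observation sequence")
    single = isinstance(log_trans, np.ndarray) and np.ndim(log_trans) == 2
    delta = log_pi + log_emis[0]
    back = np.zeros((n, s), dtype=np.intp)
    for t in range(1, n):
        a = log_trans if single else log_trans[t - 1]
        scores = delta[:, None] + a
        # argmax returns the first (lowest) index on ties
        best = np.argmax(scores, axis=0)
        back[t] = best
        delta = scores[best, np.arange(s)] + log_emis[t]
    path = np.empty(n, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def viterbi_decode(snps: pd.DataFrame, model: HMMModel,
                   emissions: EmissionTable | None = None) -> np.ndarray:
    """Decode one chromosome of SNPs to per-SNP state indices.

    ``snps`` needs columns position/baf/lrr and optionally pb (population
    B-allele frequency; defaults to 0.5, which only matters for telling LOH
    from normal at rare-allele SNPs). Positions must be strictly increasing.
    Pass the :class:`EmissionTable` of a mixed model to decode a
    stroma-contaminated sample.
    """
    if len(snps) == 0:
        raise ValueError("no SNPs to decode")
    pos = np.asarray(snps["position"], dtype=float)
    if len(pos) > 1 and not (np.diff(pos) > 0).all():
        raise ValueError("SNP positions must be strictly increasing within a chromosome")
    p_b = (np.asarray(snps["pb"], dtype=float) if "pb" in snps
           else np.full(len(snps), 0.5))
    log_emis = log_emission_matrix(
        np.asarray(snps["baf"], dtype=float),
        np.asarray(snps["lrr"], dtype=float),
        p_b, model, emissions,
    )
    log_pi = np.log(model.stationary())
    dists = np.diff(pos)
    cache: dict[float, np.ndarray] = {}
    log_trans = []
    for d in dists:
        if d not in cache:
            cache[d] = np.log(np.maximum(transition_matrix(d, model),
                                         DENSITY_FLOOR))
        log_trans.append(cache[d])
    return viterbi_path(log_pi, log_trans, log_emis)


# ---------------------------------------------------------------------------
# segmentation and genotype calling

@dataclass(frozen=True)
class CNVRegion:
    """A maximal run of SNPs decoded to one state."""

    chrom: str
    start_pos: int      # position of the first SNP (1-based)
    end_pos: int        # position of the last SNP (1-based)
    state: str
    n_snps: int
    copy_number: int
    allelic_imbalance: float


def segment_path(path: np.ndarray, snps: pd.DataFrame,
                 model: HMMModel) -> list[CNVRegion]:
    """Collapse a per-SNP state path into maximal same-state regions."""
    if len(path) != len(snps):
        raise ValueError(f"path length {len(path)} != SNP count {len(snps)}")
    pos = np.asarray(snps["position"])
    chrom = str(snps["chrom"].iloc[0]) if "chrom" in snps else "NA"
    names = model.state_names
    regions: list[CNVRegion] = []
    starts = np.flatnonzero(np.r_[True, np.diff(path) != 0])
    bounds = np.r_[starts, len(path)]
    for a, b in zip(bounds[:-1], bounds[1:]):
        name = names[path[a]]
        cn, ai = state_cn_ai(name)
        regions.append(CNVRegion(
            chrom=chrom, start_pos=int(pos[a]), end_pos=int(pos[b - 1]),
            state=name, n_snps=int(b - a), copy_number=cn,
            allelic_imbalance=ai,
        ))
    return regions


def call_genotype(b: float, state_idx: int, model: HMMModel,
                  emissions: EmissionTable | None = None) -> str:
    """Most likely genotype string for a BAF under an assigned state.

    Evaluates the censored-Gaussian value of each genotype class at ``b``
    and returns the class with the greatest one; ties go to the genotype
    with fewer B alleles. The 'O' state has no genotype and yields the
    sentinel ``NO_GENOTYPE``.
    """
    sp = model.states[state_idx]
    if sp.state.genotype_classes is None:
        return NO_GENOTYPE
    em = model.emissions() if emissions is None else emissions
    vals = _censored_class_values(np.array([b]), em.baf_means[state_idx],
                                  em.baf_sds[state_idx])[0]
    classes = sp.state.genotype_classes
    order = sorted(range(4), key=lambda g: (classes[g].count("B"), g))
    best = max(order, key=lambda g: vals[g])   # stable: first max in order
    return classes[best]
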