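"""Emission-model update for tumor samples contaminated with stromal cells.

A biopsy is modeled as a two-component mixture: a fraction ``w`` of normal
diploid cells (state 'FM' unless overridden) and ``1 - w`` of tumor cells in
some CNV state.  Contamination does not change the hidden states or the
transition model — it moves every state's emission distributions toward the
normal state's, which is what erodes detection power as w grows.

LRR: the R score (linear intensity ratio, LRR = log2 R) of the mixture is
the w-weighted sum of the two components' R scores, each lognormal. The sum
of lognormals is approximated as lognormal by matching its first two
linear-space moments (the classic Fenton-Wilkinson approximation), giving
the mixed state's log2-space mean and SD in closed form.

BAF: a mixed genotype derives from tumor and normal genotypes of the same
germline class, so the mixed class-g BAF is the copy-number-weighted
combination with alpha = w*cN / (w*cN + (1-w)*cT) on the normal component.
Means combine linearly with (alpha, 1-alpha). SDs combine linearly too:
both "components" are read out by the same probe in one hybridization, so
the band width interpolates between the pure-tumor and pure-normal widths
rather than shrinking as independent errors would — this keeps the balanced
states ('FM', 'FFMM') exactly invariant under mixing, as observed.

The mixed copy number w*cN + (1-w)*cT and the mixed class means are shared
between genuinely different configurations — e.g. ('FFM', w=0.5) and
('FFFM', w=0.75) both give mixed CN 2.5 and identical band positions —
which is the identifiability limit of bulk two-component data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import EmissionTable, HMMModel
from .states import CNVState

__all__ = [
    "MixConfig",
    "MixedModel",
    "mix_lrr_params",
    "mixed_copy_number",
    "mix_baf_params",
    "build_mixed_model",
    "estimate_proportion",
    "shift_lrr_baseline",
    "baf_band_median",
]

logger = logging.getLogger(__name__)

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class MixConfig:
    """Sample-level contamination settings.

    w is global per sample: one dominant tumor clone mixed with normal
    cells. lrr_baseline corrects an upstream normalization shift (LRR of
    the diploid band not at 0) and is applied to the data, not the model.
    """

    w: float
    normal_state: str = "FM"
    lrr_baseline: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"stromal proportion must be in [0,1]: {self.w}")
        CNVState(self.normal_state)


@dataclass(frozen=True)
class MixedModel:
    """A base model plus its contamination-adjusted emission table.

    Quacks like :class:`HMMModel` for everything the decoder needs; the
    transition side is untouched by mixing.
    """

    base: HMMModel
    config: MixConfig
    _emissions: EmissionTable

    def emissions(self) -> EmissionTable:
        return self._emissions

    # delegate the HMMModel surface used by the decoder
    @property
    def states(self):
        return self.base.states

    @property
    def n_states(self) -> int:
        return self.base.n_states

    @property
    def state_names(self):
        return self.base.state_names

    def index(self, name: str) -> int:
        return self.base.index(name)

    @property
    def outlier_weight(self) -> float:
        return self.base.outlier_weight

    @property
    def lrr_uniform(self):
        return self.base.lrr_uniform

    @property
    def baf_uniform(self):
        return self.base.baf_uniform

    def stationary(self) -> np.ndarray:
        return self.base.stationary()

    def mean_lengths(self) -> np.ndarray:
        return self.base.mean_lengths()


def mix_lrr_params(tumor_lrr: tuple[float, float],
                   normal_lrr: tuple[float, float],
                   w: float) -> tuple[float, float]:
    """Mixed-sample LRR (mean, sd) by lognormal moment matching.

    R_mix = w*R_N + (1-w)*R_T with independent lognormal components; the
    first two linear-space moments of the sum determine the approximating
    lognormal, returned in log2 units. w = 0 and w = 1 return the tumor and
    normal parameters exactly.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"stromal proportion must be in [0,1]: {w}")
    if w == 0.0:
        return tuple(tumor_lrr)
    if w == 1.0:
        return tuple(normal_lrr)
    mu_t, sd_t = tumor_lrr
    mu_n, sd_n = normal_lrr
    if sd_t <= 0 or sd_n <= 0:
        raise ValueError("LRR standard deviations must be positive")
    # convert log2-space params to natural-log lognormal params
    m = []
    v = []
    for coef, mu, sd in ((w, mu_n, sd_n), (1.0 - w, mu_t, sd_t)):
        mu_ln, sd_ln = mu * _LN2, sd * _LN2
        mean = math.exp(mu_ln + 0.5 * sd_ln * sd_ln)
        var = mean * mean * math.expm1(sd_ln * sd_ln)
        m.append(coef * mean)
        v.append(coef * coef * var)
    mean_s = m[0] + m[1]
    var_s = v[0] + v[1]
    sd2_ln = math.log1p(var_s / (mean_s * mean_s))
    mu_ln = math.log(mean_s) - 0.5 * sd2_ln
    return (mu_ln / _LN2, math.sqrt(sd2_ln) / _LN2)


def mixed_copy_number(c_t: float, w: float, c_n: float = 2.0) -> float:
    """Apparent copy number of the mixture: w*cN + (1-w)*cT."""
    if c_t < 0:
        raise ValueError("tumor copy number must be >= 0")
    return w * c_n + (1.0 - w) * c_t


def _alpha(w: float, c_n: float, c_t: float) -> float:
    """Fraction of the allele signal contributed by the normal component."""
    denom = w * c_n + (1.0 - w) * c_t
    if denom == 0.0:            # w = 0 and tumor CN 0: no DNA at all
        return 1.0
    return w * c_n / denom


def mix_baf_params(mean_t: float, sd_t: float, mean_n: float, sd_n: float,
                   w: float, c_t: float, c_n: float = 2.0) -> tuple[float, float]:
    """Mixed BAF (mean, sd) of one genotype class.

    The copy-number weighting makes a class's band move further for states
    that contribute little DNA: a homozygous-deletion tumor (cT = 0) yields
    the normal component's band exactly for any w > 0.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"stromal proportion must be in [0,1]: {w}")
    if w == 0.0 and c_t == 0.0:
        # pure 'O': no DNA; keep the pure-model noise-band convention
        return (0.5, sd_t)
    a = _alpha(w, c_n, c_t)
    return (a * mean_n + (1.0 - a) * mean_t,
            a * sd_n + (1.0 - a) * sd_t)


def build_mixed_model(model: HMMModel, mix: MixConfig) -> MixedModel:
    """Apply the LRR and BAF mixing updates to every state and class.

    Genotype-class priors are untouched: a mixed genotype derives from
    tumor and normal genotypes of the same germline class, so the germline
    Hardy-Weinberg weights still apply.
    """
    em = model.emissions()
    w = mix.w
    n_idx = model.index(mix.normal_state)
    normal_lrr = (float(em.lrr_mean[n_idx]), float(em.lrr_sd[n_idx]))
    normal_baf_means = em.baf_means[n_idx]
    normal_baf_sds = em.baf_sds[n_idx]
    c_n = float(model.states[n_idx].state.copy_number)

    lrr_mean = np.empty(model.n_states)
    lrr_sd = np.empty(model.n_states)
    baf_means = np.empty_like(em.baf_means)
    baf_sds = np.empty_like(em.baf_sds)
    for i, sp in enumerate(model.states):
        lrr_mean[i], lrr_sd[i] = mix_lrr_params(
            (float(em.lrr_mean[i]), float(em.lrr_sd[i])), normal_lrr, w)
        c_t = float(sp.state.copy_number)
        for g in range(4):
            baf_means[i, g], baf_sds[i, g] = mix_baf_params(
                float(em.baf_means[i, g]), float(em.baf_sds[i, g]),
                float(normal_baf_means[g]), float(normal_baf_sds[g]),
                w, c_t, c_n)
    mixed = EmissionTable(lrr_mean=lrr_mean, lrr_sd=lrr_sd,
                          baf_means=baf_means, baf_sds=baf_sds)
    return MixedModel(base=model, config=mix, _emissions=mixed)


def estimate_proportion(b: float,
                        tumor_genotype: tuple[int, int],
                        normal_genotype: tuple[int, int] = (1, 2)) -> float:
    """Stromal proportion from an annotated BAF band value.

    Solves b = (w*nB_N + (1-w)*nB_T) / (w*cN + (1-w)*cT) for w, where
    (nB, c) are the B-allele count and total copy number of the tumor band
    genotype (typically 'A' in an 'F' region: (0, 1), giving w = b/(1-b);
    or 'AA' in 'FF': (0, 2), giving w = 2b) and of the normal genotype
    ('AB': (1, 2)). The band is the heterozygous-derived band between 0 and
    the normal heterozygous position — absent in a pure tumor, rising
    toward 0.5 as contamination grows.
    """
    nb_t, c_t = tumor_genotype
    nb_n, c_n = normal_genotype
    denom = b * (c_n - c_t) - nb_n + nb_t
    numer = nb_t - b * c_t
    if denom == 0.0:
        raise ValueError(
            f"band value b={b} carries no information for tumor genotype "
            f"(nB={nb_t}, CN={c_t}) vs normal (nB={nb_n}, CN={c_n})")
    w = numer / denom
    if not -1e-9 <= w <= 1.0 + 1e-9:
        if -0.25 < w < 1.25:
            logger.warning(
                "estimated proportion %.3f outside [0,1] (tumor cells may "
                "carry more DNA than normal cells); clipping", w)
        else:
            raise ValueError(
                f"band value b={b} is infeasible for tumor genotype "
                f"(nB={nb_t}, CN={c_t}): implied proportion {w:.3f}")
    return min(max(w, 0.0), 1.0)


def shift_lrr_baseline(snps: pd.DataFrame, baseline: float) -> pd.DataFrame:
    """Subtract a constant LRR baseline from every SNP (copy).

    Used when the diploid band of a sample does not sit at LRR 0; the
    baseline is the annotated median LRR of a confirmed two-copy band.
    """
    if not math.isfinite(baseline):
        raise ValueError("baseline must be finite")
    out = snps.copy()
    out["lrr"] = out["lrr"].astype(float) - baseline
    return out


def baf_band_median(baf: np.ndarray, low: float = 0.08,
                    high: float = 0.48) -> float:
    """Median of the lower heterozygous-derived BAF band.

    Helper for purity annotation: restrict to the open window between the
    homozygous band at 0 and the normal heterozygous band at 0.5, where
    the contamination-induced band of an LOH region lives.
    """
    baf = np.asarray(baf, dtype=float)
    sel = baf[(baf > low) & (baf < high)]
    if sel.size == 0:
        raise ValueError(f"no SNPs with BAF in ({low}, {high}); "
                         "sample may be a pure tumor")
    return float(np.median(sel))
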