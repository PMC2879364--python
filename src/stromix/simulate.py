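"""Synthetic mixed-sample generator with known truth.

Each simulated region is a run of SNPs in one CNV state. Per SNP the
generator draws a germline genotype class from the Hardy-Weinberg priors at
that SNP's population B-allele frequency, then draws BAF from that class's
(contamination-adjusted) Gaussian censored to [0,1], and LRR from the
state's (contamination-adjusted) Gaussian; with probability pi0 either
observation is replaced by a uniform outlier, mirroring the emission model.

SNP positions are laid out on a uniform grid (default 5 kb, the typical
spacing of a ~550k genome-wide array); the decoder sees positions only
through inter-SNP distances, so a real manifest is not required. Population
B-allele frequencies are drawn from a symmetric Beta(2, 2) — genome-wide
array content is enriched for common variants — or held at 0.5.

The default design mirrors the validation layout: one 100- or 300-SNP
region per state, all 20 states per chromosome, shuffled per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import CNVRegion
from .mixing import MixConfig, build_mixed_model
from .model import HMMModel
from .states import state_cn_ai

__all__ = ["SimLayout", "simulate_sample", "shuffled_genome_layout"]

DEFAULT_SPACING = 5_000     # bp between adjacent simulated SNPs
N_AUTOSOMES = 22


@dataclass(frozen=True)
class SimLayout:
    """Blueprint of a simulated sample.

    regions maps each chromosome to an ordered list of (state name,
    n_snps). pb_beta gives the Beta(a, a) shape for population B-allele
    frequencies; None fixes them all at 0.5.
    """

    regions: dict[str, list[tuple[str, int]]]
    w: float = 0.0
    seed: int = 0
    spacing: int = DEFAULT_SPACING
    start: int = 1_000_000
    starts: tuple[tuple[str, int], ...] | None = None   # per-chrom overrides
    pb_beta: float | None = 2.0
    simulate_outliers: bool = True

    def chrom_start(self, chrom: str) -> int:
        if self.starts is not None:
            for c, s in self.starts:
                if c == chrom:
                    return s
        return self.start

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"stromal proportion must be in [0,1]: {self.w}")
        for chrom, regs in self.regions.items():
            for name, n in regs:
                if n < 1:
                    raise ValueError(f"region of {n} SNPs on {chrom}")


def shuffled_genome_layout(region_len: int, seed: int, w: float = 0.0,
                           model: HMMModel | None = None,
                           n_chrom: int = N_AUTOSOMES,
                           **kwargs) -> SimLayout:
    """One region per state on every autosome, order shuffled per chromosome.

    With the 20-state model this yields n_chrom x 20 regions (440 on 22
    autosomes), each ``region_len`` SNPs long; the chromosomal offset also
    varies by chromosome so region boundaries do not align across
    chromosomes.
    """
    from .model import default_model
    model = model or default_model()
    names = list(model.state_names)
    rng = np.random.default_rng(seed)
    regions: dict[str, list[tuple[str, int]]] = {}
    starts = []
    for c in range(1, n_chrom + 1):
        order = rng.permutation(len(names))
        regions[str(c)] = [(names[i], region_len) for i in order]
        starts.append((str(c),
                       1_000_000 + int(rng.integers(0, 200)) * DEFAULT_SPACING))
    return SimLayout(regions=regions, w=w, seed=seed, starts=tuple(starts),
                     **kwargs)


def _simulate_chromosome(chrom: str, regs: list[tuple[str, int]],
                         model, em, pi0: float, layout: SimLayout,
                         rng: np.random.Generator):
    n_total = sum(n for _, n in regs)
    pos = layout.chrom_start(chrom) + layout.spacing * np.arange(n_total)
    if layout.pb_beta is None:
        pb = np.full(n_total, 0.5)
    else:
        pb = rng.beta(layout.pb_beta, layout.pb_beta, size=n_total)
    state_idx = np.concatenate([
        np.full(n, model.index(name), dtype=np.intp) for name, n in regs])

    means = em.baf_means[state_idx]          # (N, 4)
    sds = em.baf_sds[state_idx]
    q = 1.0 - pb
    w_cls = np.stack([q * q, pb * pb, pb * q, pb * q], axis=1)
    cum = np.cumsum(w_cls, axis=1)
    u = rng.random(n_total)
    cls = (u[:, None] > cum).sum(axis=1).clip(0, 3)
    baf = rng.normal(means[np.arange(n_total), cls],
                     sds[np.arange(n_total), cls]).clip(0.0, 1.0)
    lrr = rng.normal(em.lrr_mean[state_idx], em.lrr_sd[state_idx])
    if layout.simulate_outliers and pi0 > 0:
        out_b = rng.random(n_total) < pi0
        out_r = rng.random(n_total) < pi0
        baf[out_b] = rng.uniform(*model.baf_uniform, size=int(out_b.sum()))
        lrr[out_r] = rng.uniform(*model.lrr_uniform, size=int(out_r.sum()))

    names = model.state_names
    snps = pd.DataFrame({
        "name": [f"snp_{chrom}_{i}" for i in range(n_total)],
        "chrom": chrom,
        "position": pos,
        "baf": baf,
        "lrr": lrr,
        "pb": pb,
    })
    cn_ai = [state_cn_ai(names[i]) for i in state_idx]
    truth = pd.DataFrame({
        "chrom": chrom,
        "position": pos,
        "state": [names[i] for i in state_idx],
        "cn": [c for c, _ in cn_ai],
        "ai": [a for _, a in cn_ai],
    })
    return snps, truth


def simulate_sample(layout: SimLayout,
                    model: HMMModel) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (snp table, per-SNP truth table) for a layout.

    Both tables are sorted by (chrom, position); the truth table carries
    per-SNP state name, copy number and allelic imbalance. Reproducible
    from ``layout.seed``.
    """
    for regs in layout.regions.values():
        for name, _ in regs:
            model.index(name)      # raises KeyError on unknown state
    mixed = build_mixed_model(model, MixConfig(w=layout.w))
    em = mixed.emissions()
    pi0 = model.outlier_weight
    rng = np.random.default_rng(layout.seed)
    snp_parts, truth_parts = [], []
    for chrom in sorted(layout.regions, key=_chrom_key):
        s, t = _simulate_chromosome(chrom, layout.regions[chrom],
                                    model, em, pi0, layout, rng)
        snp_parts.append(s)
        truth_parts.append(t)
    snps = pd.concat(snp_parts, ignore_index=True)
    truth = pd.concat(truth_parts, ignore_index=True)
    return snps, truth


def truth_regions(truth: pd.DataFrame) -> list[CNVRegion]:
    """Collapse a per-SNP truth table into true regions (per chromosome)."""
    regions: list[CNVRegion] = []
    for chrom, grp in truth.groupby("chrom", sort=False):
        states = grp["state"].to_numpy()
        pos = grp["position"].to_numpy()
        starts = np.flatnonzero(np.r_[True, states[1:] != states[:-1]])
        bounds = np.r_[starts, len(states)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            cn, ai = state_cn_ai(states[a])
            regions.append(CNVRegion(
                chrom=str(chrom), start_pos=int(pos[a]), end_pos=int(pos[b - 1]),
                state=str(states[a]), n_snps=int(b - a),
                copy_number=cn, allelic_imbalance=ai))
    return regions


def _chrom_key(c: str):
    return (0, int(c)) if str(c).isdigit() else (1, str(c))
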