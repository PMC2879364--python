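"""End-to-end detection: per-chromosome Viterbi over a whole sample."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hmm import CNVRegion, segment_path, viterbi_decode
from .mixing import MixConfig, build_mixed_model, shift_lrr_baseline
from .model import HMMModel
from .states import state_cn_ai

__all__ = ["detect_sample"]


def detect_sample(snps: pd.DataFrame, model: HMMModel,
                  mix: MixConfig | None = None
                  ) -> tuple[list[CNVRegion], pd.DataFrame]:
    """Decode every chromosome of a sample.

    Applies the LRR baseline shift and, for w > 0, the stromal-mixing
    emission update, then runs Viterbi independently per chromosome (state
    paths do not cross centromeres of different chromosomes by
    construction: each chromosome restarts from the stationary
    distribution).

    Returns (region calls, per-SNP frame with state/cn/ai) aligned with the
    input row order after per-chromosome sorting.
    """
    mix = mix or MixConfig(w=0.0)
    if mix.lrr_baseline != 0.0:
        snps = shift_lrr_baseline(snps, mix.lrr_baseline)
    decode_model = build_mixed_model(model, mix) if mix.w > 0 else model
    emissions = decode_model.emissions()

    regions: list[CNVRegion] = []
    frames = []
    for chrom, grp in snps.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        path = viterbi_decode(grp, model, emissions)
        regions.extend(segment_path(path, grp, model))
        names = [model.state_names[i] for i in path]
        cn_ai = [state_cn_ai(n) for n in names]
        frames.append(pd.DataFrame({
            "chrom": str(chrom),
            "position": grp["position"].to_numpy(),
            "state": names,
            "cn": np.array([c for c, _ in cn_ai]),
            "ai": np.array([a for _, a in cn_ai]),
        }))
    return regions, pd.concat(frames, ignore_index=True)
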