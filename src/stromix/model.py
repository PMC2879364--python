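"""HMM parameter set and its plain-text model file.

A model holds, per hidden state: the stationary probability pi (the expected
proportion of SNPs in that state), the mean genomic length L of regions in
that state, the LRR Gaussian (mean, SD), and the Gaussian of the g3 BAF
genotype class (germline-AB-derived, A-majority). Everything else is derived:

* g1 (all-A) takes the g3 parameters of the LOH state with the same copy
  number, whose g3 genotype *is* all-A;
* g2 and g4 mirror g1 and g3 about BAF = 0.5;
* the homozygous-deletion state 'O' has no genotypes — its BAF is a single
  noise band at 0.5, represented by four identical pseudo-classes so that
  the stromal-mixing update (which acts per class) applies uniformly.

A global outlier weight pi0 and the two uniform supports complete the model.
All parameters are user-editable through the text format written by
:func:`write_model`; the packaged ``data/fm20.hmm`` is the default 20-state
model serialized with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

from .states import CNVState, enumerate_states

__all__ = [
    "StateParams",
    "HMMModel",
    "EmissionTable",
    "default_model",
    "read_model",
    "write_model",
]

# Default LRR band centers per copy number (dimensionless log2-ratio units).
# 'O' at -4 reflects background signal; the rest follow a saturating curve
# anchored at 0 for the diploid state.
DEFAULT_LRR_MEAN = {0: -4.0, 1: -0.66, 2: 0.0, 3: 0.40, 4: 0.68,
                    5: 0.89, 6: 1.06, 7: 1.21}
DEFAULT_LRR_SD = {0: 1.0, 1: 0.22, 2: 0.18, 3: 0.20, 4: 0.21,
                  5: 0.23, 6: 0.24, 7: 0.25}
#: BAF band SDs typical of Illumina BeadArray data.
BAF_SD_HOM = 0.02     # homozygous bands (g3 of an LOH state)
BAF_SD_HET = 0.04     # heterozygous-derived bands
BAF_SD_NULL = 0.20    # 'O': no DNA, BAF is noise around 0.5


@dataclass(frozen=True)
class StateParams:
    """All tunable parameters of one hidden state."""

    state: CNVState
    pi: float                 # stationary probability (proportion of SNPs)
    mean_region_len: float    # mean length L of regions in this state (bp)
    lrr_mean: float
    lrr_sd: float
    baf_g3_mean: float        # equals the state's MCP in the default model
    baf_g3_sd: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError(f"pi must be in (0,1): {self.pi}")
        if self.mean_region_len <= 0:
            raise ValueError("mean_region_len must be positive")
        if self.lrr_sd <= 0 or self.baf_g3_sd <= 0:
            raise ValueError("standard deviations must be positive")


@dataclass(frozen=True)
class EmissionTable:
    """Per-state emission distributions, fully resolved.

    ``baf_means``/``baf_sds`` have shape (n_states, 4), one column per
    genotype class g1..g4.  A mixed-sample model is just another
    EmissionTable, so the decoder is agnostic to contamination.
    """

    lrr_mean: np.ndarray      # (n,)
    lrr_sd: np.ndarray        # (n,)
    baf_means: np.ndarray     # (n, 4)
    baf_sds: np.ndarray       # (n, 4)


@dataclass(frozen=True)
class HMMModel:
    states: tuple[StateParams, ...]
    outlier_weight: float = 0.01
    lrr_uniform: tuple[float, float] = (-6.0, 3.0)
    baf_uniform: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.outlier_weight < 1.0:
            raise ValueError("outlier_weight must be in [0,1)")
        total = sum(sp.pi for sp in self.states)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"state stationary probabilities sum to {total}, not 1")
        if self.lrr_uniform[0] >= self.lrr_uniform[1]:
            raise ValueError("empty LRR uniform support")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(sp.state.name for sp in self.states)

    def index(self, name: str) -> int:
        try:
            return self.state_names.index(name)
        except ValueError:
            raise KeyError(f"state {name!r} not in model") from None

    def stationary(self) -> np.ndarray:
        return np.array([sp.pi for sp in self.states])

    def mean_lengths(self) -> np.ndarray:
        return np.array([sp.mean_region_len for sp in self.states])

    def emissions(self) -> EmissionTable:
        """Resolve the four BAF genotype-class Gaussians of every state."""
        n = self.n_states
        # g3 params of the LOH state, per copy number, define the
        # homozygous band width of that copy number.
        loh_g3: dict[int, tuple[float, float]] = {}
        for sp in self.states:
            if sp.state.is_loh:
                loh_g3[sp.state.copy_number] = (sp.baf_g3_mean, sp.baf_g3_sd)
        means = np.empty((n, 4))
        sds = np.empty((n, 4))
        for i, sp in enumerate(self.states):
            if sp.state.genotype_classes is None:     # 'O'
                means[i] = sp.baf_g3_mean
                sds[i] = sp.baf_g3_sd
                continue
            cn = sp.state.copy_number
            if cn not in loh_g3:
                raise ValueError(
                    f"model lacks the LOH state for copy number {cn}, needed "
                    f"to derive homozygous-band parameters of {sp.state.name!r}"
                )
            m1, s1 = loh_g3[cn]
            m3, s3 = sp.baf_g3_mean, sp.baf_g3_sd
            means[i] = (m1, 1.0 - m1, m3, 1.0 - m3)   # g2/g4 mirror g1/g3
            sds[i] = (s1, s1, s3, s3)
        return EmissionTable(
            lrr_mean=np.array([sp.lrr_mean for sp in self.states]),
            lrr_sd=np.array([sp.lrr_sd for sp in self.states]),
            baf_means=means,
            baf_sds=sds,
        )


def default_model(max_cn: int = 7, pi_normal: float = 0.70,
                  len_normal: float = 1e8, len_aberrant: float = 5e6) -> HMMModel:
    """The shipped 20-state model (copy numbers 0..7).

    The normal state 'FM' holds the bulk of the stationary mass and has a
    ~100 Mb characteristic region length; the aberrant states split the
    remainder equally with ~5 Mb regions. Detection is robust to these
    transition-side parameters; the emission side carries the signal.
    """
    states = enumerate_states(max_cn)
    n_aber = len(states) - 1
    pi_aber = (1.0 - pi_normal) / n_aber
    params = []
    for st in states:
        cn = st.copy_number
        if st.name == "O":
            g3_mean, g3_sd = 0.5, BAF_SD_NULL
        elif st.is_loh:
            g3_mean, g3_sd = 0.0, BAF_SD_HOM
        else:
            g3_mean, g3_sd = float(st.mcp), BAF_SD_HET
        normal = st.name == "FM"
        params.append(StateParams(
            state=st,
            pi=pi_normal if normal else pi_aber,
            mean_region_len=len_normal if normal else len_aberrant,
            lrr_mean=DEFAULT_LRR_MEAN[cn],
            lrr_sd=DEFAULT_LRR_SD[cn],
            baf_g3_mean=g3_mean,
            baf_g3_sd=g3_sd,
        ))
    return HMMModel(states=tuple(params))


# ---------------------------------------------------------------------------
# text format

_HEADER_KEYS = ("outlier_weight", "lrr_uniform", "baf_uniform")
_COLUMNS = ("state", "pi", "mean_region_len", "lrr_mean", "lrr_sd",
            "baf_g3_mean", "baf_g3_sd")


def write_model(model: HMMModel, path: str | Path) -> None:
    """Serialize a model to the documented tab-delimited text format."""
    lines = [
        f"outlier_weight\t{model.outlier_weight:.17g}",
        f"lrr_uniform\t{model.lrr_uniform[0]:.17g}\t{model.lrr_uniform[1]:.17g}",
        f"baf_uniform\t{model.baf_uniform[0]:.17g}\t{model.baf_uniform[1]:.17g}",
        "\t".join(_COLUMNS),
    ]
    for sp in model.states:
        lines.append("\t".join([
            sp.state.name,
            f"{sp.pi:.17g}", f"{sp.mean_region_len:.17g}",
            f"{sp.lrr_mean:.17g}", f"{sp.lrr_sd:.17g}",
            f"{sp.baf_g3_mean:.17g}", f"{sp.baf_g3_sd:.17g}",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def _nonempty_lines(text: str) -> Iterable[str]:
    for raw in text.splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            yield line


def read_model(path: str | Path) -> HMMModel:
    """Parse a model file written by :func:`write_model`."""
    header: dict[str, tuple[float, ...]] = {}
    states: list[StateParams] = []
    in_table = False
    for line in _nonempty_lines(Path(path).read_text()):
        parts = line.split("\t")
        if not in_table and parts[0] in _HEADER_KEYS:
            header[parts[0]] = tuple(float(x) for x in parts[1:])
            continue
        if parts[0] == "state":          # column header starts the table
            if tuple(parts) != _COLUMNS:
                raise ValueError(f"unexpected model table columns: {parts}")
            in_table = True
            continue
        if not in_table:
            raise ValueError(f"unrecognized model file line: {line!r}")
        if len(parts) != len(_COLUMNS):
            raise ValueError(f"model row has {len(parts)} fields: {line!r}")
        states.append(StateParams(
            state=CNVState(parts[0]),
            pi=float(parts[1]),
            mean_region_len=float(parts[2]),
            lrr_mean=float(parts[3]),
            lrr_sd=float(parts[4]),
            baf_g3_mean=float(parts[5]),
            baf_g3_sd=float(parts[6]),
        ))
    if not states:
        raise ValueError(f"no states found in model file {path}")
    kwargs: dict = {}
    if "outlier_weight" in header:
        kwargs["outlier_weight"] = header["outlier_weight"][0]
    for key in ("lrr_uniform", "baf_uniform"):
        if key in header:
            lo, hi = header[key]
            kwargs[key] = (lo, hi)
    return HMMModel(states=tuple(states), **kwargs)


def packaged_model() -> HMMModel:
    """Load the default model from the packaged ``data/fm20.hmm`` file."""
    ref = resources.files("stromix").joinpath("data/fm20.hmm")
    with resources.as_file(ref) as p:
        return read_model(p)
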