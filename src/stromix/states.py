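"""Chromosomal-aberration state space for allele-specific CNV calling.

Each hidden state describes the somatic configuration of the two parental
homologs, written as a word over {F, M} ('F' the retained/major homolog,
'M' the minor one), or the single letter 'O' for homozygous deletion.
Because a genotyping array cannot tell 'FMM' from 'FFM', state names always
carry at least as many F's as M's, with the F's written first.

A state is fully characterised by its copy number CN = #F + #M and its
minor-copy proportion MCP = #M / CN; the allelic imbalance AI = 1/2 - MCP
ranges from 0 (balanced, #F = #M) to 1/2 (LOH, no M at all).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

__all__ = [
    "CNVState",
    "enumerate_states",
    "get_state",
    "state_cn_ai",
    "genotype_class_priors",
    "NULL_STATE",
]

NULL_STATE = "O"

#: AI reported for the homozygous-deletion state, whose MCP is undefined.
#: 1/2 groups it with the LOH states on an AI track; settable per call.
DEFAULT_NULL_AI = 0.5


def _validate_name(name: str) -> tuple[int, int]:
    """Return (#F, #M) for a state name, raising on malformed input."""
    if name == NULL_STATE:
        return (0, 0)
    if not name or set(name) - {"F", "M"}:
        raise ValueError(f"invalid CNV state name: {name!r}")
    n_f = name.count("F")
    n_m = len(name) - n_f
    if n_m > n_f:
        raise ValueError(
            f"state {name!r} has more M's than F's; indistinguishable states "
            f"are written with F's first (e.g. 'FFM', not 'FMM')"
        )
    if name != "F" * n_f + "M" * n_m:
        raise ValueError(f"state name must list F's before M's: {name!r}")
    return (n_f, n_m)


@dataclass(frozen=True)
class CNVState:
    """One hidden state: an F/M word (or 'O') plus derived quantities.

    The four genotype classes g1..g4 are grouped by germline origin:
    g1 from germline AA (tumor genotype A^CN), g2 from BB (B^CN), g3 from
    AB keeping A in the majority (#B = #M), g4 its mirror (#A = #M).
    'O' carries no genotypes.
    """

    name: str
    copy_number: int = field(init=False)
    mcp: Fraction | None = field(init=False)
    allelic_imbalance: Fraction = field(init=False)
    genotype_classes: tuple[str, str, str, str] | None = field(init=False)

    def __post_init__(self) -> None:
        n_f, n_m = _validate_name(self.name)
        cn = n_f + n_m
        object.__setattr__(self, "copy_number", cn)
        if self.name == NULL_STATE:
            object.__setattr__(self, "mcp", None)
            object.__setattr__(self, "allelic_imbalance", Fraction(1, 2))
            object.__setattr__(self, "genotype_classes", None)
            return
        mcp = Fraction(n_m, cn)
        object.__setattr__(self, "mcp", mcp)
        object.__setattr__(self, "allelic_imbalance", Fraction(1, 2) - mcp)
        g1 = "A" * cn
        g2 = "B" * cn
        g3 = "A" * n_f + "B" * n_m
        g4 = "A" * n_m + "B" * n_f
        object.__setattr__(self, "genotype_classes", (g1, g2, g3, g4))

    @property
    def is_loh(self) -> bool:
        """No minor homolog left: only homozygous genotypes observable."""
        return self.name != NULL_STATE and "M" not in self.name

    @property
    def is_balanced(self) -> bool:
        return self.mcp == Fraction(1, 2)

    def distinct_genotypes(self) -> tuple[str, ...]:
        """Distinct genotype strings, sorted by B count (BAF band order)."""
        if self.genotype_classes is None:
            return ()
        return tuple(sorted(set(self.genotype_classes), key=lambda g: g.count("B")))


def enumerate_states(max_cn: int) -> list[CNVState]:
    """All distinguishable states with copy number up to ``max_cn``.

    Returns 'O' followed by every word F^a M^b with a >= b >= 0 and
    1 <= a+b <= max_cn, ordered by copy number then by increasing minor-copy
    proportion (LOH state first within each copy number). The shipped
    default model uses max_cn=7, giving 20 states; max_cn=4 gives 9.
    """
    if max_cn < 0:
        raise ValueError("max_cn must be >= 0")
    out = [CNVState(NULL_STATE)]
    for cn in range(1, max_cn + 1):
        for n_m in range(0, cn // 2 + 1):
            out.append(CNVState("F" * (cn - n_m) + "M" * n_m))
    return out


def get_state(name: str) -> CNVState:
    """Construct (and validate) a single state by name."""
    return CNVState(name)


def state_cn_ai(name: str, null_ai: float = DEFAULT_NULL_AI) -> tuple[int, float]:
    """Copy number and allelic imbalance of a state: CN = #F + #M,
    AI = 1/2 - #M/CN.  For 'O' (CN 0, MCP undefined) AI is ``null_ai``."""
    st = CNVState(name)
    if st.name == NULL_STATE:
        return (0, float(null_ai))
    return (st.copy_number, float(st.allelic_imbalance))


def genotype_class_priors(p_b: float) -> tuple[float, float, float, float]:
    """Probability of each genotype class g1..g4 given the population
    B-allele frequency ``p_b``.

    Every somatic state is assumed to derive from the germline 'FM' state,
    so the class weights are the Hardy-Weinberg germline genotype
    frequencies: ((1-pB)^2, pB^2, pB(1-pB), pB(1-pB)).
    """
    if not 0.0 <= p_b <= 1.0:
        raise ValueError(f"population B-allele frequency must be in [0,1]: {p_b}")
    p_a = 1.0 - p_b
    return (p_a * p_a, p_b * p_b, p_b * p_a, p_b * p_a)
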