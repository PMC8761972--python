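"""Blunt-cutter digestion, blunt-end ligation and one-step cloning simulation.

The workhorse enzyme is SmaI (CCC^GGG, blunt).  Insertion of a fragment at
the cut destroys the recognition site whereas self-ligation of the vector
restores it — the property that makes a combined digestion–ligation
("one-step", single-tube) reaction self-selecting: re-circularised empty
vectors are recut while insert-carrying products are immune to further
digestion.  :func:`simulate_one_step` models the colony population that
results, with the recutting captured by a single probability ``p_recut``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from pgrass.seqcore import CIRCULAR, LINEAR, NucSeq, reverse_complement

SELF = "self"
FORWARD = "forward"
REVERSE = "reverse"
KINDS = (SELF, FORWARD, REVERSE)


class NoCutSiteError(ValueError):
    """The enzyme does not cut the given sequence."""


class MultipleCutSitesError(ValueError):
    """More than one recognition site where a unique cutter is required."""


class IncompatibleEndsError(ValueError):
    """Blunt ligation attempted on non-blunt or circular substrates."""


class OneStepIneligibleError(ValueError):
    """Insert carries an internal recognition site; single-tube cloning would recut it."""


@dataclass(frozen=True)
class Enzyme:
    """A symmetric blunt-cutting restriction enzyme.

    ``cut_offset`` is the position of the cut within the recognition
    sequence on the top strand; blunt cutters cut both strands at the same
    offset, so the recognition site must be its own reverse complement.
    """

    name: str
    recognition: str
    cut_offset: int
    end_type: str = "blunt"

    def __post_init__(self) -> None:
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside recognition sequence")
        if self.end_type != "blunt":
            raise ValueError("only blunt cutters are modelled")
        if reverse_complement(self.recognition) != self.recognition:
            raise ValueError(
                f"{self.name}: blunt symmetric cutter needs a palindromic site"
            )


#: CCC^GGG — cut geometry from standard enzyme references.
SMA_I = Enzyme("SmaI", "CCCGGG", 3)


@dataclass(frozen=True)
class BluntFragment:
    """A linear double-stranded fragment with two blunt, unphosphatased ends."""

    seq: NucSeq
    enzyme: Enzyme = SMA_I

    def __post_init__(self) -> None:
        if self.seq.is_circular:
            raise IncompatibleEndsError("a fragment with ends must be linear")

    @property
    def ends(self) -> str:
        return self.enzyme.end_type


@dataclass(frozen=True)
class LigationProduct:
    """One circular outcome of a blunt ligation reaction.

    ``kind`` is one of ``self`` / ``forward`` / ``reverse``; junction 6-mers
    record the sequence spanning each new phosphodiester joint so that
    re-created recognition sites can be detected (``regenerated_site_count``).
    """

    kind: str
    seq: NucSeq
    junction_5p: str
    junction_3p: str
    regenerated_site_count: int

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown ligation kind {self.kind!r}")


@dataclass(frozen=True)
class OneStepParams:
    """Parameters of the single-tube digestion–ligation colony model.

    ``p_recut`` is the probability that a restored recognition site (a
    self-ligation) is digested again before transformation; 1.0 reflects an
    enzyme excess under which only insert-containing circles survive.
    ``w_self``/``w_ins`` are the relative propensities of self- vs
    insert-ligation events; no measured ratio is available so both default
    to 1.
    """

    n_colonies: int = 100
    p_recut: float = 1.0
    orientation_bias: float = 0.5
    rng_seed: int = 0
    w_self: float = 1.0
    w_ins: float = 1.0

    def __post_init__(self) -> None:
        if self.n_colonies < 1:
            raise ValueError("n_colonies must be >= 1")
        for name in ("p_recut", "orientation_bias"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.w_self < 0 or self.w_ins < 0:
            raise ValueError("ligation weights must be non-negative")


def find_sites(seq: NucSeq, enzyme: Enzyme = SMA_I) -> list[tuple[int, int]]:
    """All top-strand occurrences of the recognition site.

    Returns ``(site_start, cut_position)`` pairs, 0-based.  On circular
    sequences sites spanning the origin are found and positions reported
    modulo length; ``cut_position = site_start + cut_offset (mod length)``.
    """
    site = enzyme.recognition
    n = len(seq)
    if seq.is_circular and n >= len(site):
        # scan the doubled string, keep starts within one period
        text = seq.bases + seq.bases[: len(site) - 1]
    else:
        text = seq.bases
    hits: list[tuple[int, int]] = []
    start = text.find(site)
    while start != -1:
        cut = start + enzyme.cut_offset
        if seq.is_circular:
            hits.append((start % n, cut % n))
        else:
            hits.append((start, cut))
        start = text.find(site, start + 1)
    return hits


def digest(vector: NucSeq, enzyme: Enzyme = SMA_I) -> BluntFragment:
    """Linearise a circular vector at its unique recognition site.

    The returned fragment starts at the cut position, so its two blunt ends
    are the two halves of the destroyed site.  Zero sites or more than one
    site raise (the vector design assumes a unique cloning site).
    """
    if not vector.is_circular:
        raise ValueError("digestion to a single fragment requires a circular substrate")
    sites = find_sites(vector, enzyme)
    if not sites:
        raise NoCutSiteError(f"{enzyme.name} does not cut {vector.id or 'vector'}")
    if len(sites) > 1:
        raise MultipleCutSitesError(
            f"{enzyme.name} cuts {vector.id or 'vector'} at {len(sites)} sites; "
            "a unique site is required"
        )
    _, cut = sites[0]
    linear = NucSeq(vector.rotated(cut).bases, LINEAR, vector.id)
    return BluntFragment(linear, enzyme)


def _junction_site_count(product_bases: str, junctions: Sequence[int], enzyme: Enzyme) -> int:
    """Count recognition sites in windows spanning each junction of a circle."""
    n = len(product_bases)
    k = len(enzyme.recognition)
    doubled = product_bases + product_bases
    count = 0
    for j in junctions:
        for start in range(j - k + 1, j):
            if doubled[start % n: start % n + k] == enzyme.recognition:
                count += 1
                break  # one site per junction
    return count


def _junction_word(product_bases: str, junction: int, width: int = 6) -> str:
    n = len(product_bases)
    half = width // 2
    doubled = product_bases + product_bases
    return doubled[(junction - half) % n: (junction - half) % n + width]


def ligate_blunt(
    vector_linear: BluntFragment,
    insert: NucSeq | None = None,
) -> list[LigationProduct]:
    """Circularise a blunt-ended vector, alone or around a blunt insert.

    Without an insert the single product is the self-ligation, which restores
    the recognition site and is rotation-identical to the undigested vector.
    With an insert both orientations are returned (blunt ligation is
    orientation-agnostic): *forward* places the insert's given strand on the
    vector's top strand immediately downstream of the cut, *reverse* ligates
    its reverse complement.  Unphosphorylated-insert chemistry admits at most
    one insert per circle, so concatemers are not modelled.
    """
    enzyme = vector_linear.enzyme
    vec = vector_linear.seq.bases
    if insert is None:
        product = NucSeq(vec, CIRCULAR, vector_linear.seq.id)
        word = _junction_word(vec, 0)
        count = _junction_site_count(vec, [0], enzyme)
        return [LigationProduct(SELF, product, word, word, count)]
    if insert.is_circular:
        raise IncompatibleEndsError("insert must be a linear blunt fragment")
    products = []
    for kind, ins in ((FORWARD, insert.bases), (REVERSE, reverse_complement(insert.bases))):
        bases = vec + ins
        product = NucSeq(bases, CIRCULAR, f"{vector_linear.seq.id}+{insert.id or 'insert'}")
        junctions = [len(vec), 0]  # vector end|insert start, insert end|vector start
        products.append(
            LigationProduct(
                kind,
                product,
                _junction_word(bases, len(vec)),
                _junction_word(bases, 0),
                _junction_site_count(bases, junctions, enzyme),
            )
        )
    return products


@dataclass(frozen=True)
class OneStepResult:
    """Colony population from a simulated single-tube digestion–ligation."""

    kinds: tuple[str, ...]
    params: OneStepParams

    @property
    def counts(self) -> dict[str, int]:
        return {k: sum(1 for x in self.kinds if x == k) for k in KINDS}

    def fraction(self, kind: str) -> float:
        return self.counts[kind] / len(self.kinds)

    def colony_table(self) -> pd.DataFrame:
        """Per-colony table consumed by the screening module / CLI."""
        return pd.DataFrame(
            {
                "colony_id": np.arange(1, len(self.kinds) + 1),
                "kind": self.kinds,
                "phenotype": [""] * len(self.kinds),
            }
        )


def simulate_one_step(
    vector: NucSeq,
    insert: NucSeq,
    params: OneStepParams,
    enzyme: Enzyme = SMA_I,
) -> OneStepResult:
    """Sample the colony population of a one-step cloning reaction.

    Each colony derives independently from one circularisation event.  A
    self-ligation restores the recognition site and survives the enzyme with
    probability ``1 − p_recut``; insert-containing circles always survive.
    Surviving outcomes are drawn with relative weights
    ``{self: w_self·(1−p_recut), forward: bias·w_ins, reverse: (1−bias)·w_ins}``.
    Deterministic under ``params.rng_seed``.
    """
    if find_sites(insert, enzyme):
        raise OneStepIneligibleError(
            f"insert contains a {enzyme.name} site; use the two-step workflow "
            "(separate digestion with enzyme removal before ligation)"
        )
    # vector must itself be a valid unique-cutter substrate
    digest(vector, enzyme)
    w = np.array(
        [
            params.w_self * (1.0 - params.p_recut),
            params.orientation_bias * params.w_ins,
            (1.0 - params.orientation_bias) * params.w_ins,
        ]
    )
    total = w.sum()
    if total <= 0:
        raise ValueError("no ligation outcome has positive weight")
    rng = np.random.default_rng(params.rng_seed)
    kinds = rng.choice(np.array(KINDS), size=params.n_colonies, p=w / total)
    return OneStepResult(tuple(kinds.tolist()), params)
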