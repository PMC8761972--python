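"""Deterministic synthetic-input generators.

Random ORFs with controlled codon content, CDS datasets with planted
target-codon fractions, unique-cutter toy plasmids, and (by delegation)
simulated qPCR curves.  Every generator is reproducible bit-for-bit under a
fixed seed.  These generators model codon *constraints*, not realistic
codon-usage bias.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from pgrass.codon_survey import CdsRecord
from pgrass.olivar import build_reference_model, enumerate_target_codons
from pgrass.qpcr import AmplificationCurve, simulate_qpcr
from pgrass.restriction import SMA_I, Enzyme, find_sites
from pgrass.seqcore import CIRCULAR, LINEAR, STOP_CODONS, NucSeq, Orf

ALL_CODONS = frozenset("".join(c) for c in itertools.product("ACGT", repeat=3))
SENSE_CODONS = ALL_CODONS - STOP_CODONS

_ATTEMPT_CAP = 10_000
_REPAIR_CAP = 1_000


class GenerationError(RuntimeError):
    """The constraint set is unsatisfiable (or pathologically tight)."""


@dataclass(frozen=True)
class OrfSpec:
    """Constraints for one random ORF.

    ``require_codons`` must each appear at least once in frame;
    ``forbid_codons`` never appear (stop codons are always forbidden in the
    body; a terminal stop is added when ``terminal_stop`` is set);
    ``forbid_motifs`` are substrings excluded anywhere, across codon
    boundaries included.  ``gc_target`` biases acceptance towards the given
    GC fraction (±0.05).
    """

    n_codons: int
    require_codons: frozenset[str] = frozenset()
    forbid_codons: frozenset[str] = frozenset()
    forbid_motifs: frozenset[str] = frozenset()
    gc_target: float | None = None
    terminal_stop: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "require_codons", frozenset(self.require_codons))
        object.__setattr__(self, "forbid_codons", frozenset(self.forbid_codons))
        object.__setattr__(self, "forbid_motifs", frozenset(self.forbid_motifs))
        if self.n_codons < 2:
            raise ValueError("n_codons must be >= 2 (start codon plus body)")
        if self.require_codons & self.forbid_codons:
            raise ValueError("require_codons and forbid_codons overlap")
        if self.require_codons & STOP_CODONS:
            raise ValueError("cannot require a stop codon in the ORF body")


def _pool(spec: OrfSpec) -> list[str]:
    pool = sorted(SENSE_CODONS - spec.forbid_codons)
    if not pool:
        raise GenerationError("all sense codons forbidden: spec unsatisfiable")
    return pool


def _violates(bases: str, spec: OrfSpec) -> bool:
    return any(m in bases for m in spec.forbid_motifs)


def _gc_ok(bases: str, spec: OrfSpec) -> bool:
    if spec.gc_target is None:
        return True
    gc = (bases.count("G") + bases.count("C")) / len(bases)
    return abs(gc - spec.gc_target) <= 0.05


def random_orf(spec: OrfSpec) -> Orf:
    """An ORF of ``spec.n_codons`` codons starting ATG, meeting all constraints.

    Rejection sampling with an attempt cap, then targeted repair (required
    codons written into random in-frame body positions), so feasible specs
    always succeed and pathological ones fail fast with
    :class:`GenerationError`.
    """
    rng = np.random.default_rng(spec.rng_seed)
    pool = _pool(spec)
    n_body = spec.n_codons - 1 - (1 if spec.terminal_stop else 0)
    if n_body < len(spec.require_codons):
        raise GenerationError("not enough body codons to place all required codons")
    terminal = ["TAA"] if spec.terminal_stop else []

    def assemble(body: list[str]) -> str:
        return "".join(["ATG", *body, *terminal])

    for _ in range(_ATTEMPT_CAP):
        body = list(rng.choice(pool, size=n_body))
        bases = assemble(body)
        if (
            spec.require_codons <= set(body)
            and not _violates(bases, spec)
            and _gc_ok(bases, spec)
        ):
            return Orf(NucSeq(bases, LINEAR, "random_orf"), has_terminal_stop=spec.terminal_stop)

    # repair: force required codons into place, keep motif/GC constraints
    for _ in range(_REPAIR_CAP):
        body = list(rng.choice(pool, size=n_body))
        slots = rng.choice(n_body, size=len(spec.require_codons), replace=False)
        for slot, codon in zip(slots, sorted(spec.require_codons)):
            body[slot] = codon
        bases = assemble(body)
        if not _violates(bases, spec) and _gc_ok(bases, spec):
            return Orf(NucSeq(bases, LINEAR, "random_orf"), has_terminal_stop=spec.terminal_stop)
    raise GenerationError(f"no ORF satisfying {spec} found; spec likely unsatisfiable")


def random_cds_set(
    n_genes: int,
    fraction_with_target: float,
    rng_seed: int = 0,
    target_codons: frozenset[str] | None = None,
    min_codons: int = 20,
    max_codons: int = 60,
) -> list[CdsRecord]:
    """A CDS dataset in which exactly ``round(n·fraction)`` genes carry a target codon.

    Genes are complete CDSs (terminal stop included) of random lengths;
    order is shuffled so the planted fraction is not positionally encoded.
    """
    if not 0.0 <= fraction_with_target <= 1.0:
        raise ValueError("fraction_with_target must be in [0, 1]")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    targets = frozenset(target_codons or enumerate_target_codons())
    rng = np.random.default_rng(rng_seed)
    n_with = round(n_genes * fraction_with_target)
    records = []
    for i in range(n_genes):
        with_target = i < n_with
        n_codons = int(rng.integers(min_codons, max_codons + 1))
        spec = OrfSpec(
            n_codons=n_codons,
            require_codons=frozenset([str(rng.choice(sorted(targets)))]) if with_target else frozenset(),
            forbid_codons=frozenset() if with_target else targets,
            terminal_stop=True,
            rng_seed=int(rng.integers(0, 2**31)),
        )
        orf = random_orf(spec)
        records.append(CdsRecord(f"g{i + 1:04d}", NucSeq(orf.bases, LINEAR, f"g{i + 1:04d}")))
    order = rng.permutation(n_genes)
    return [records[j] for j in order]


def random_unique_cutter_vector(
    rng_seed: int = 0,
    length: int = 300,
    enzyme: Enzyme = SMA_I,
) -> NucSeq:
    """A random circular plasmid with exactly one recognition site."""
    site = enzyme.recognition
    if length < len(site) + 1:
        raise ValueError("vector too short to host a recognition site")
    rng = np.random.default_rng(rng_seed)
    for _ in range(1000):
        rest = "".join(rng.choice(list("ACGT"), size=length - len(site)))
        pos = int(rng.integers(0, len(rest) + 1))
        vec = NucSeq(rest[:pos] + site + rest[pos:], CIRCULAR, "toy_vector")
        if len(find_sites(vec, enzyme)) == 1:
            return vec
    raise GenerationError("failed to build a unique-cutter vector")


def reference_vector(rng_seed: int = 0):
    """The seeded reference screening-vector model (see :mod:`pgrass.olivar`)."""
    return build_reference_model(rng_seed)


def qpcr_curves(
    template_ratio: float = 3.0,
    efficiency: float = 2.0,
    noise_sd: float = 0.01,
    n_replicates: int = 3,
    rng_seed: int = 0,
) -> list[AmplificationCurve]:
    """Simulated qPCR curve set (delegates to :func:`pgrass.qpcr.simulate_qpcr`)."""
    return simulate_qpcr(
        template_ratio,
        E_p=efficiency,
        E_c=efficiency,
        noise_sd=noise_sd,
        n_replicates=n_replicates,
        rng_seed=rng_seed,
    )
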