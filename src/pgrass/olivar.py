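"""Antisense-reporter orientation screening: cassette model and phenotype logic.

The vector couples two cassettes in opposing orientations on one plasmid:

* **Selection cassette (SC)** — weak constitutive promoter, GFP reporter and
  terminator.  Its translation start sits *downstream* (in SC reading
  direction) of the expression cassette, so the SC ribosome reads antisense
  through the entire expression cassette before reaching GFP.
* **Expression cassette (EC)** — strong inducible promoter, translation
  start, a unique blunt cloning site, six histidine codons and a stop.  The
  EC sequence is designed to be free of stop codons in the antisense reading
  frame, so with no insert (self-ligation) the SC ribosome reads through and
  colonies fluoresce.

An ORF ligated at the cloning site in the *correct* orientation (relative to
the EC promoter) is read antisense by the SC ribosome; any in-frame TCA, TTA
or CTA codon of the insert then appears as a stop (TGA, TAA, TAG) on the SC
transcript, truncating translation before GFP — colonies go dark.  The same
ORF in *reverse* orientation is read in sense and, being stop-free, produces
an insert→GFP fusion — colonies stay green.  Colony colour therefore selects
both for insert presence and for its orientation.

Everything here is recomputed from sequence: the validator re-derives frames
and stop content from the plasmid bases, and phenotype prediction simulates
SC-strand translation of the actual ligation-product sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from pgrass.restriction import (
    FORWARD,
    REVERSE,
    SELF,
    SMA_I,
    Enzyme,
    LigationProduct,
    find_sites,
)
from pgrass.seqcore import (
    CIRCULAR,
    STOP_CODONS,
    FrameError,
    NucSeq,
    Orf,
    codons,
    reverse_complement,
    translate_codon,
)

FLUORESCENT = "fluorescent"
NON_FLUORESCENT = "non_fluorescent"
LOW_FLUORESCENT = "low_fluorescent"

SC_READTHROUGH = "sc_readthrough_no_insert"
FUSION_READTHROUGH = "fusion_readthrough_reverse_insert"
PREMATURE_ANTISENSE_STOP = "premature_antisense_stop"
DESTABILIZED_FUSION = "destabilized_fusion"

STRONG = "strong"
WEAK_DESTABILIZATION = "weak_destabilization"


class ModelStructureError(ValueError):
    """The vector model's coordinates are internally inconsistent."""


def enumerate_target_codons() -> frozenset[str]:
    """All trinucleotides whose reverse complement is a standard-code stop.

    Derived by enumeration over the 64 codons rather than hard-coded; the
    result is {TCA, TTA, CTA}, the screening-enabling codons.
    """
    return frozenset(
        "".join(c)
        for c in itertools.product("ACGT", repeat=3)
        if reverse_complement("".join(c)) in STOP_CODONS
    )


@dataclass(frozen=True)
class ScreenPolicy:
    """Rules governing phenotype calls.

    ``target_codons`` are the sense codons read as stops on the antisense
    strand; ``low_fluorescence_rule`` controls whether a correct-orientation,
    target-codon-free insert is called *low* fluorescent (N-terminal junk
    peptide destabilising the GFP fusion) or left fluorescent.
    """

    target_codons: frozenset[str] = field(default_factory=enumerate_target_codons)
    low_fluorescence_rule: str = "destabilized_fusion_on"

    def __post_init__(self) -> None:
        for c in self.target_codons:
            if reverse_complement(c) not in STOP_CODONS:
                raise ValueError(f"{c} is not the reverse complement of a stop codon")
        if self.low_fluorescence_rule not in ("destabilized_fusion_on", "off"):
            raise ValueError("low_fluorescence_rule must be destabilized_fusion_on or off")

    @property
    def low_rule_on(self) -> bool:
        return self.low_fluorescence_rule == "destabilized_fusion_on"


@dataclass(frozen=True)
class ScreenReport:
    """Predicted colony phenotype for one ligation product, with mechanism."""

    phenotype: str
    reason: str
    stop_codon_index: int | None = None
    fusion_layout: str | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.stop_codon_index is not None) != (self.reason == PREMATURE_ANTISENSE_STOP):
            raise ValueError("stop_codon_index present iff reason is premature_antisense_stop")


@dataclass(frozen=True)
class ScreenabilityReport:
    """How well an insert ORF supports one-step cloning and screening."""

    one_step_eligible: bool
    antisense_stop_count: int
    first_antisense_stop_codon_index: int | None
    screening_mode: str
    internal_stop_in_orf: bool
    frame_ok: bool

    def __post_init__(self) -> None:
        if (self.screening_mode == STRONG) != (self.antisense_stop_count >= 1):
            raise ValueError("screening_mode strong iff >=1 antisense stop")


@dataclass(frozen=True)
class VectorModel:
    """Annotated circular plasmid with SC/EC landmarks.

    All coordinates are 0-based on the stored (EC-sense) top strand; minus-
    strand elements occupy ``[start, end)`` with their 5' end at ``end``.
    ``sc_start`` is the top-strand index of the SC start codon's image (the
    triplet reading CAT); the SC frame runs leftwards from there.
    """

    seq: NucSeq
    sc_start: int
    gfp_orf: tuple[int, int]
    ec_start: int
    smaI_cut: int
    his6: tuple[int, int]
    ec_stop: int
    terminators: dict[str, tuple[int, int]] = field(default_factory=dict)
    promoters: dict[str, tuple[int, int]] = field(default_factory=dict)
    lac_operator: tuple[int, int] | None = None
    sc_strand: int = -1
    ec_strand: int = 1

    def __post_init__(self) -> None:
        if not self.seq.is_circular:
            raise ModelStructureError("vector must be circular")
        if self.sc_strand == self.ec_strand:
            raise ModelStructureError("SC and EC must be on opposite strands")
        n = len(self.seq)
        for name, pos in (("sc_start", self.sc_start), ("ec_start", self.ec_start),
                          ("smaI_cut", self.smaI_cut), ("ec_stop", self.ec_stop)):
            if not 0 <= pos < n:
                raise ModelStructureError(f"{name}={pos} out of range for length {n}")

    def sc_codon(self, j: int, in_seq: NucSeq | None = None, sc_start: int | None = None) -> str:
        """The j-th codon of the SC reading frame (j=0 is the SC start codon)."""
        seq = in_seq if in_seq is not None else self.seq
        anchor = self.sc_start if sc_start is None else sc_start
        start = (anchor - 3 * j) % len(seq)
        return reverse_complement(seq.fragment(start, start + 3))


def antisense_stop_positions(orf: "Orf | NucSeq", policy: ScreenPolicy | None = None) -> list[int]:
    """Codon indices (in the ORF's own frame) that stop antisense translation.

    A codon flagged here reads as a stop when the insert sits antisense to
    the SC transcript, i.e. when the gene is cloned in the correct
    orientation for expression.
    """
    policy = policy or ScreenPolicy()
    bases = orf.bases if isinstance(orf, (Orf, NucSeq)) else str(orf)
    if len(bases) % 3 != 0:
        raise FrameError(f"length {len(bases)} is not a multiple of 3")
    return [i for i, c in enumerate(codons(bases)) if c in policy.target_codons]


# ---------------------------------------------------------------------------
# Reference model construction
# ---------------------------------------------------------------------------

# Triplets safe on the EC (top) strand within the SC read-through region:
# not a stop in their own frame and not a stop when reverse-complemented.
# CCC/GGG excluded to keep accidental SmaI sites rare (a global uniqueness
# check still runs after assembly).
_SAFE_TRIPLETS = sorted(
    {"".join(c) for c in itertools.product("ACGT", repeat=3)}
    - STOP_CODONS
    - enumerate_target_codons()
    - {"CCC", "GGG"}
)

_HIS_CODONS = ("CAC", "CAT")


def _safe_triplets(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_SAFE_TRIPLETS, size=n))


def _filler(rng: np.random.Generator, n: int, forbidden: str) -> str:
    while True:
        s = "".join(rng.choice(list("ACGT"), size=n))
        if forbidden not in s:
            return s


def build_reference_model(rng_seed: int = 0) -> VectorModel:
    """A synthetic ~3.6 kb plasmid satisfying every cassette constraint.

    Stand-in for a real annotated vector map: promoters, operator, RBS and
    terminators are placeholder sequences (feature labels carry the
    biological identity), but every frame and stop-codon constraint the
    screening logic relies on is enforced by construction and re-checked by
    :func:`validate_cassette`.  Deterministic under ``rng_seed``.
    """
    for attempt in range(100):
        rng = np.random.default_rng((int(rng_seed) + 1_000_003 * attempt) % 2**31)
        model = _assemble_reference(rng)
        sites = find_sites(model.seq, SMA_I)
        if len(sites) == 1 and sites[0][1] == model.smaI_cut:
            return model
    raise RuntimeError("could not assemble a unique-cutter reference vector")


def _assemble_reference(rng: np.random.Generator) -> VectorModel:
    site = SMA_I.recognition  # CCCGGG, cut at codon boundary between CCC and GGG
    sc_term = _safe_triplets(rng, 8)            # rrnB T1 placeholder (minus strand)
    gfp = "ATG" + _safe_triplets(rng, 118) + "TAA"   # toy GFP ORF (minus strand)
    m2 = _safe_triplets(rng, 4)                 # SC-frame linker, promoter→GFP
    p_t7 = _safe_triplets(rng, 6)
    lac_o = _safe_triplets(rng, 6)
    rbs = _safe_triplets(rng, 3)
    ec_pre = _safe_triplets(rng, 4)             # EC codons upstream of the cut
    ec_post = _safe_triplets(rng, 4)            # EC codons downstream of the cut
    his6 = "".join(_HIS_CODONS[i % 2] for i in range(6))
    t7_term = _safe_triplets(rng, 8)
    sc_prom = _safe_triplets(rng, 8)            # P_lacIq placeholder (minus strand)
    f1 = _filler(rng, 1400, site)
    f2 = _filler(rng, 1300, site)

    parts: list[tuple[str, str]] = [
        ("F1", f1),
        ("rrnB_T1", reverse_complement(sc_term)),
        ("GFP", reverse_complement(gfp)),
        ("M2", reverse_complement(m2)),
        ("P_T7", p_t7),
        ("lacO", lac_o),
        ("RBS", rbs),
        ("EC_ATG", "ATG"),
        ("EC_pre", ec_pre),
        ("site", site),
        ("EC_post", ec_post),
        ("6xHis", his6),
        ("EC_stop", "TAA"),
        ("T7_term", t7_term),
        ("SC_ATG", reverse_complement("ATG")),
        ("P_lacIq", reverse_complement(sc_prom)),
        ("F2", f2),
    ]
    pos: dict[str, tuple[int, int]] = {}
    cursor = 0
    chunks = []
    for name, bases in parts:
        pos[name] = (cursor, cursor + len(bases))
        chunks.append(bases)
        cursor += len(bases)
    plasmid = NucSeq("".join(chunks), CIRCULAR, "pRef")
    return VectorModel(
        seq=plasmid,
        sc_start=pos["SC_ATG"][0],
        gfp_orf=pos["GFP"],
        ec_start=pos["EC_ATG"][0],
        smaI_cut=pos["site"][0] + SMA_I.cut_offset,
        his6=pos["6xHis"],
        ec_stop=pos["EC_stop"][0],
        terminators={"rrnB_T1": pos["rrnB_T1"], "T7_term": pos["T7_term"]},
        promoters={"P_lacIq": pos["P_lacIq"], "P_T7": pos["P_T7"]},
        lac_operator=pos["lacO"],
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_cassette(model: VectorModel, policy: ScreenPolicy | None = None) -> list[str]:
    """Check the design constraints the screening logic depends on.

    Returns a list of human-readable violations (empty iff the model is a
    valid screening vector).  Checks, all recomputed from the sequence:

    a. no stop codon in the SC reading frame from the SC start through the
       last codon before GFP (the antisense read-through corridor);
    b. the cloning enzyme cuts exactly once, at ``smaI_cut``;
    c. frame congruence — a 3n insert at the cut stays in frame with the EC
       start/His6/stop and, antisense, with the SC start and GFP;
    d. the EC ORF ends in exactly six histidine codons followed by a stop.
    """
    del policy  # reserved: violations are policy-independent for now
    seq = model.seq
    n = len(seq)
    violations: list[str] = []

    if reverse_complement(seq.fragment(model.sc_start, model.sc_start + 3)) != "ATG":
        raise ModelStructureError("no ATG at sc_start on the SC strand")
    if seq.fragment(model.ec_start, model.ec_start + 3) != "ATG":
        raise ModelStructureError("no ATG at ec_start on the EC strand")
    g0, g1 = model.gfp_orf
    if (g1 - g0) % 3 != 0 or g1 <= g0:
        raise ModelStructureError("GFP interval is not a codon-aligned interval")

    # (c) frame congruence at the cut, both frames
    if (model.smaI_cut - model.ec_start) % 3 != 0:
        violations.append("frame: smaI_cut out of frame with the EC start")
    if (model.sc_start - model.smaI_cut) % 3 != 0:
        violations.append("frame: smaI_cut out of frame with the SC start")
    d = (model.sc_start + 3 - g1) % n  # SC-strand distance, SC ATG -> GFP ATG
    if d % 3 != 0:
        violations.append("frame: GFP out of frame with the SC start")
    if (model.his6[0] - model.ec_start) % 3 != 0 or (model.ec_stop - model.ec_start) % 3 != 0:
        violations.append("frame: His6/stop out of frame with the EC start")

    # (a) SC read-through corridor must be stop-free up to (not including) GFP
    if d % 3 == 0:
        n_pre = d // 3
        for j in range(n_pre):
            codon = model.sc_codon(j)
            if codon in STOP_CODONS:
                violations.append(
                    f"antisense frame: stop codon {codon} at SC codon {j} before GFP"
                )
    # GFP itself must translate cleanly on the SC strand
    gfp_sc = reverse_complement(seq.fragment(g0, g1))
    gfp_stops = [i for i, c in enumerate(codons(gfp_sc)) if c in STOP_CODONS]
    if not gfp_sc.startswith("ATG") or gfp_stops != [len(gfp_sc) // 3 - 1]:
        violations.append("GFP ORF malformed on the SC strand")

    # (b) unique cloning site at the annotated cut
    sites = find_sites(seq, SMA_I)
    if len(sites) != 1:
        violations.append(f"cloning site: expected 1 {SMA_I.name} site, found {len(sites)}")
    elif sites[0][1] != model.smaI_cut:
        violations.append(
            f"cloning site: {SMA_I.name} cuts at {sites[0][1]}, annotated at {model.smaI_cut}"
        )

    # (d) EC product: ... H H H H H H *
    h0, h1 = model.his6
    his_codons = list(codons(seq.fragment(h0, h1)))
    if len(his_codons) != 6 or any(translate_codon(c) != "H" for c in his_codons):
        violations.append("His-tag: his6 interval does not encode six histidines")
    if seq.fragment(model.ec_stop, model.ec_stop + 3) not in STOP_CODONS:
        violations.append("His-tag: no stop codon at ec_stop")
    if model.ec_stop != h1:
        violations.append("His-tag: stop does not immediately follow the His6 run")
    prev = seq.fragment(h0 - 3, h0)
    if translate_codon(prev) == "H":
        violations.append("His-tag: histidine run longer than six codons")
    # EC ORF between start and stop must be open (no internal stop)
    ec_len = (model.ec_stop - model.ec_start) % n
    if ec_len % 3 == 0:
        ec_orf = seq.fragment(model.ec_start, model.ec_start + ec_len)
        internal = [i for i, c in enumerate(codons(ec_orf)) if c in STOP_CODONS]
        if internal:
            violations.append(f"EC ORF: internal stop at codon {internal[0]}")
    return violations


# ---------------------------------------------------------------------------
# Phenotype prediction
# ---------------------------------------------------------------------------

def _find_unique(circle: NucSeq, probe: str) -> int:
    """Start of the unique occurrence of ``probe`` on a circular sequence."""
    n = len(circle)
    text = circle.bases + circle.bases[: len(probe) - 1]
    hits = []
    i = text.find(probe)
    while i != -1:
        hits.append(i % n)
        i = text.find(probe, i + 1)
    hits = sorted(set(hits))
    if len(hits) != 1:
        raise ValueError(f"anchor occurs {len(hits)} times in product; cannot localise")
    return hits[0]


def predict_gfp_outcome(
    model: VectorModel,
    product: LigationProduct,
    insert: "Orf | NucSeq | None" = None,
    policy: ScreenPolicy | None = None,
) -> ScreenReport:
    """Predict colony fluorescence for one ligation product.

    The call simulates SC-strand translation of the *actual* product
    sequence: the SC start codon and the GFP ORF are located in the product
    by unique sequence anchors taken from the model, the reading frame is
    walked codon by codon, and the phenotype follows from whether
    translation reaches the end of GFP before hitting a stop.  Product kind
    labels are used only to phrase the mechanistic reason, never to decide
    the phenotype.
    """
    policy = policy or ScreenPolicy()
    if validate_cassette(model):
        raise ModelStructureError("model fails cassette validation; fix before predicting")
    if (product.kind == SELF) != (insert is None):
        raise ValueError("insert must be given exactly when the product carries one")

    warnings: list[str] = []
    ins_bases: str | None = None
    if insert is not None:
        ins_bases = insert.bases if isinstance(insert, (Orf, NucSeq)) else str(insert)
        if len(ins_bases) % 3 != 0:
            raise FrameError("insert length must be a multiple of 3 for frame-aware screening")
        own_stops = [i for i, c in enumerate(codons(ins_bases)) if c in STOP_CODONS]
        if own_stops:
            warnings.append(
                f"insert carries internal stop(s) at codon {own_stops}: "
                "reverse-orientation screening is compromised"
            )
    if product.regenerated_site_count:
        warnings.append(
            f"{product.regenerated_site_count} recognition site(s) regenerated at "
            "ligation junction(s): product is not immune to re-digestion"
        )

    seq = model.seq
    n = len(seq)
    prod = product.seq
    npz = len(prod)
    # anchors drawn from regions the cloning reaction never disturbs
    sc_anchor = seq.fragment(model.sc_start, model.sc_start + 30)
    sc_new = _find_unique(prod, sc_anchor)
    g0, g1 = model.gfp_orf
    gfp_probe = seq.fragment(g0, g1)
    gfp_new_end = _find_unique(prod, gfp_probe) + (g1 - g0)
    n_gfp = (g1 - g0) // 3

    d = (sc_new + 3 - gfp_new_end) % npz
    if d % 3 != 0:
        raise FrameError("ligation product breaks the SC/GFP frame congruence")
    n_pre = d // 3

    first_stop: int | None = None
    for j in range(n_pre + n_gfp):
        if model.sc_codon(j, in_seq=prod, sc_start=sc_new) in STOP_CODONS:
            first_stop = j
            break
    reaches_gfp_end = first_stop == n_pre + n_gfp - 1  # the GFP terminal stop

    if reaches_gfp_end:
        if insert is None:
            return ScreenReport(FLUORESCENT, SC_READTHROUGH, warnings=tuple(warnings))
        name = getattr(insert, "id", "") or getattr(getattr(insert, "seq", None), "id", "") or "insert"
        if product.kind == REVERSE:
            return ScreenReport(
                FLUORESCENT, FUSION_READTHROUGH,
                fusion_layout=f"{name}→GFP", warnings=tuple(warnings),
            )
        # correct orientation, no antisense stop: junk N-terminal peptide on GFP
        phenotype = LOW_FLUORESCENT if policy.low_rule_on else FLUORESCENT
        return ScreenReport(
            phenotype, DESTABILIZED_FUSION,
            fusion_layout=f"antisense({name})→GFP", warnings=tuple(warnings),
        )

    # premature termination before GFP: locate the stop within the insert
    stop_index = None
    if ins_bases is not None:
        junction_anchor = seq.fragment(model.smaI_cut - 30, model.smaI_cut)
        p0 = (_find_unique(prod, junction_anchor) + 30) % npz
        li = len(ins_bases)
        stops_in_insert = []
        for j in range(n_pre):
            if model.sc_codon(j, in_seq=prod, sc_start=sc_new) in STOP_CODONS:
                top_start = (sc_new - 3 * j) % npz
                offset = (top_start - p0) % npz
                if offset < li:
                    if product.kind == FORWARD:
                        stops_in_insert.append(offset // 3)
                    else:
                        stops_in_insert.append((li - 3 - offset) // 3)
        if stops_in_insert:
            stop_index = min(stops_in_insert)
    if stop_index is None:
        # stop outside any insert: report the SC-frame position instead
        return ScreenReport(
            NON_FLUORESCENT, PREMATURE_ANTISENSE_STOP,
            stop_codon_index=first_stop, warnings=tuple(warnings) + ("stop outside insert region",),
        )
    return ScreenReport(
        NON_FLUORESCENT, PREMATURE_ANTISENSE_STOP,
        stop_codon_index=stop_index, warnings=tuple(warnings),
    )


def classify_insert(
    orf: "Orf | NucSeq",
    policy: ScreenPolicy | None = None,
    enzyme: Enzyme = SMA_I,
) -> ScreenabilityReport:
    """Summarise whether an ORF supports one-step cloning and strong screening."""
    policy = policy or ScreenPolicy()
    seq = orf.seq if isinstance(orf, Orf) else orf
    frame_ok = len(seq) % 3 == 0
    one_step = not find_sites(seq, enzyme)
    if frame_ok:
        positions = antisense_stop_positions(seq, policy)
        internal_stop = any(c in STOP_CODONS for c in codons(seq.bases))
    else:
        positions = []
        internal_stop = False
    return ScreenabilityReport(
        one_step_eligible=one_step,
        antisense_stop_count=len(positions),
        first_antisense_stop_codon_index=positions[0] if positions else None,
        screening_mode=STRONG if positions else WEAK_DESTABILIZATION,
        internal_stop_in_orf=internal_stop,
        frame_ok=frame_ok,
    )


# ---------------------------------------------------------------------------
# GenBank round trip for annotated vector maps
# ---------------------------------------------------------------------------

_FEATURES = {
    "SC_start": "misc_feature",
    "EC_start": "misc_feature",
    "EC_stop": "misc_feature",
    "GFP": "CDS",
    "SmaI": "misc_feature",
    "6xHis": "misc_feature",
    "lacO": "misc_feature",
}


def model_to_genbank(model: VectorModel, path: str | Path) -> None:
    """Write the vector map as an annotated GenBank record."""
    record = SeqRecord(
        Seq(model.seq.bases),
        id=model.seq.id or "vector",
        name=(model.seq.id or "vector")[:16],
        description="antisense-reporter screening vector",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )

    def add(label: str, start: int, end: int, strand: int, ftype: str) -> None:
        record.features.append(
            SeqFeature(FeatureLocation(start, end, strand=strand),
                       type=ftype, qualifiers={"label": [label]})
        )

    add("SC_start", model.sc_start, model.sc_start + 3, model.sc_strand, "misc_feature")
    add("EC_start", model.ec_start, model.ec_start + 3, model.ec_strand, "misc_feature")
    add("EC_stop", model.ec_stop, model.ec_stop + 3, model.ec_strand, "misc_feature")
    add("GFP", *model.gfp_orf, model.sc_strand, "CDS")
    add("SmaI", model.smaI_cut - SMA_I.cut_offset, model.smaI_cut - SMA_I.cut_offset + 6,
        model.ec_strand, "misc_feature")
    add("6xHis", *model.his6, model.ec_strand, "misc_feature")
    if model.lac_operator:
        add("lacO", *model.lac_operator, model.ec_strand, "misc_feature")
    for name, iv in model.promoters.items():
        add(name, *iv, model.sc_strand if name == "P_lacIq" else model.ec_strand, "promoter")
    for name, iv in model.terminators.items():
        add(name, *iv, model.sc_strand if name == "rrnB_T1" else model.ec_strand, "terminator")
    SeqIO.write(record, str(path), "genbank")


def model_from_genbank(path: str | Path) -> VectorModel:
    """Rebuild a :class:`VectorModel` from labelled GenBank features.

    Recognised labels: SC_start, EC_start, EC_stop, GFP (CDS), SmaI, 6xHis,
    lacO, plus promoter and terminator features carrying their own labels.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = NucSeq(str(record.seq), CIRCULAR, record.id)
    found: dict[str, tuple[int, int]] = {}
    promoters: dict[str, tuple[int, int]] = {}
    terminators: dict[str, tuple[int, int]] = {}
    for f in record.features:
        label = (f.qualifiers.get("label") or [""])[0]
        iv = (int(f.location.start), int(f.location.end))
        if f.type == "promoter":
            promoters[label] = iv
        elif f.type == "terminator":
            terminators[label] = iv
        elif label:
            found[label] = iv
    missing = {"SC_start", "EC_start", "EC_stop", "GFP", "SmaI", "6xHis"} - set(found)
    if missing:
        raise ModelStructureError(f"GenBank map lacks labelled features: {sorted(missing)}")
    return VectorModel(
        seq=seq,
        sc_start=found["SC_start"][0],
        gfp_orf=found["GFP"],
        ec_start=found["EC_start"][0],
        smaI_cut=found["SmaI"][0] + SMA_I.cut_offset,
        his6=found["6xHis"],
        ec_stop=found["EC_stop"][0],
        terminators=terminators,
        promoters=promoters,
        lac_operator=found.get("lacO"),
    )
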