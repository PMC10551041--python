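"""Golden-Gate oligo construction, Type IIS digestion simulation, and
multiplex mini-CRISPR array assembly.

Enzyme geometry (BsaI GGTCTC / Esp3I CGTCTC): the enzyme cuts outside its
recognition site, 1 nt downstream on the top strand and 5 nt downstream on
the bottom strand, leaving programmable 4-nt 5' overhangs.

The shipped default priming sequences and overhangs are synthetic stand-ins:
real cassette sequences are supplied through the config file, never
hard-coded (only the enzyme recognition sites are constants).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .genome_io import revcomp

ENZYME_SITES = {"BsaI": "GGTCTC", "Esp3I": "CGTCTC"}


class SpacerRejectedError(ValueError):
    """Structured rejection: the spacer cannot go into this cassette."""

    def __init__(self, spacer: str, motif: str, position: int):
        self.spacer, self.motif, self.position = spacer, motif, position
        super().__init__(
            f"spacer contains {motif} at position {position}; rejected (no silent fix)"
        )


@dataclass(frozen=True)
class FlankConfig:
    """Golden-Gate cassette flanks. Defaults are synthetic stand-ins."""

    prime5: str = "ACCTGTTCGACAGTCAGTCA"
    prime3: str = "TGCTGACTGTCGAACAGGTT"
    enzyme: str = "BsaI"
    overhang5: str = "AACA"
    overhang3: str = "GTTT"
    spacer_site_offset: int = 1  # nt between recognition site and cut

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYME_SITES:
            raise ValueError(f"enzyme must be one of {sorted(ENZYME_SITES)}")
        if len(self.overhang5) != 4 or len(self.overhang3) != 4:
            raise ValueError("overhangs must be 4 nt")
        site = ENZYME_SITES[self.enzyme]
        for name, seq in (("prime5", self.prime5), ("prime3", self.prime3)):
            if site in seq or revcomp(site) in seq:
                raise ValueError(f"{name} contains the {self.enzyme} site")

    @property
    def site(self) -> str:
        return ENZYME_SITES[self.enzyme]


@dataclass(frozen=True)
class OligoConstruct:
    guide_id: str
    oligo: str
    spacer: str
    flanks: FlankConfig

    @property
    def length(self) -> int:
        return len(self.oligo)


def _contains_site(seq: str, site: str) -> int:
    """Position of the first enzyme site in seq (either orientation), or -1."""
    for motif in (site, revcomp(site)):
        i = seq.find(motif)
        if i != -1:
            return i
    return -1


def make_oligo(guide, flanks: FlankConfig | None = None) -> OligoConstruct:
    """prime5 + site + N + overhang5 + spacer + overhang3 + N + rc(site) + prime3.

    The spacer must be free of the enzyme's recognition site; violations are
    a structured rejection. Colliding or palindromic overhangs only warn.
    """
    flanks = flanks or FlankConfig()
    spacer = guide if isinstance(guide, str) else guide.spacer
    guide_id = guide if isinstance(guide, str) else guide.guide_id
    pos = _contains_site(spacer, flanks.site)
    if pos != -1:
        motif = flanks.site if flanks.site in spacer else revcomp(flanks.site)
        raise SpacerRejectedError(spacer, motif, spacer.find(motif))
    if flanks.overhang5 == flanks.overhang3:
        warnings.warn("overhang5 == overhang3: ligation orientation is ambiguous", stacklevel=2)
    for oh in (flanks.overhang5, flanks.overhang3):
        if oh == revcomp(oh):
            warnings.warn(f"palindromic overhang {oh}: self-ligation possible", stacklevel=2)
    filler = "A" * flanks.spacer_site_offset
    oligo = (
        flanks.prime5
        + flanks.site
        + filler
        + flanks.overhang5
        + spacer
        + flanks.overhang3
        + filler
        + revcomp(flanks.site)
        + flanks.prime3
    )
    # construction invariants
    if oligo.count(spacer) != 1:
        raise SpacerRejectedError(spacer, "duplicate-spacer-context", 0)
    assert oligo.count(flanks.site) == 1 and oligo.count(revcomp(flanks.site)) == 1
    return OligoConstruct(guide_id, oligo, spacer, flanks)


@dataclass(frozen=True)
class Fragment:
    """Top-strand span of a digestion fragment.

    ``left_overhang``/``right_overhang`` are the 4-nt 5' overhangs at the
    fragment boundaries ('' at the oligo ends). ``released`` extends the
    top-strand sequence through the downstream overhang, so the insert
    fragment of a Golden-Gate oligo reads overhang5 + spacer + overhang3.
    """

    seq: str
    start: int
    end: int
    left_overhang: str
    right_overhang: str

    @property
    def released(self) -> str:
        return self.seq + self.right_overhang


def simulate_digest(oligo: str, enzyme: str = "BsaI") -> list[Fragment]:
    """Cut a linear oligo at every Type IIS site; fragments cover the input.

    Forward sites (site at p) cut top at p+7 / bottom at p+11; reverse sites
    (rc(site) at q) cut top at q-5 / bottom at q-1. Cuts falling outside the
    molecule are ignored. No site -> one uncut fragment.
    """
    site = ENZYME_SITES[enzyme]
    n = len(oligo)
    tops: list[int] = []
    i = oligo.find(site)
    while i != -1:
        t = i + len(site) + 1
        if 0 < t and t + 4 <= n:
            tops.append(t)
        i = oligo.find(site, i + 1)
    rc = revcomp(site)
    i = oligo.find(rc)
    while i != -1:
        t = i - 5
        if 0 < t and t + 4 <= n:
            tops.append(t)
        i = oligo.find(rc, i + 1)
    tops = sorted(set(tops))
    bounds = [0, *tops, n]
    frags = []
    for a, b in zip(bounds, bounds[1:]):
        frags.append(
            Fragment(
                seq=oligo[a:b],
                start=a,
                end=b,
                left_overhang=oligo[a : a + 4] if a != 0 else "",
                right_overhang=oligo[b : b + 4] if b != n else "",
            )
        )
    return frags


def golden_gate_insert(construct: OligoConstruct) -> str:
    """The overhang5+spacer+overhang3 piece released by digestion."""
    frags = simulate_digest(construct.oligo, construct.flanks.enzyme)
    if len(frags) != 3:
        raise ValueError(f"expected 3 fragments, digestion gave {len(frags)}")
    return frags[1].released


def ligate(left: str, insert: str, right: str, overhang5: str, overhang3: str) -> str:
    """Join a released insert into a receiver; overhangs must match exactly.

    ``left`` must end with overhang5 and ``right`` start with overhang3 (the
    receiver exposes complementary 5' overhangs); the product is the simple
    concatenation of receiver arms around the interior of the insert.
    """
    if not insert.startswith(overhang5) or not insert.endswith(overhang3):
        raise ValueError("insert overhangs do not match the requested junction")
    if not left.endswith(overhang5) or not right.startswith(overhang3):
        raise ValueError("receiver overhangs do not match")
    return left + insert[4:-4] + right


@dataclass(frozen=True)
class CrisprArray:
    """Repeat-led alternation R S1 R S2 ... Sn R (n spacers, n+1 repeats)."""

    repeat: str
    spacers: tuple[str, ...]
    promoter_label: str | None = None

    @property
    def assembled(self) -> str:
        return self.repeat + "".join(s + self.repeat for s in self.spacers)

    @property
    def n_repeats(self) -> int:
        return len(self.spacers) + 1


def build_array(
    spacers,
    repeat: str,
    promoter_label: str | None = None,
    max_spacers: int = 10,
    allow_mixed_modes: bool = False,
    mode_boundary: int = 26,
) -> CrisprArray:
    """Assemble a multiplex mini-CRISPR array from spacers or GuideDesigns."""
    if not repeat:
        raise ValueError("repeat must be configured (no default sequence is shipped)")
    seqs: list[str] = []
    modes: set[str] = set()
    for s in spacers:
        if isinstance(s, str):
            seq = s
            modes.add("repression" if len(s) <= mode_boundary else "cleavage")
        else:
            seq = s.spacer
            modes.add(s.mode)
        if not seq:
            raise ValueError("empty spacer")
        seqs.append(seq)
    if not (1 <= len(seqs) <= max_spacers):
        raise ValueError(f"need 1..{max_spacers} spacers, got {len(seqs)}")
    if len(modes) > 1 and not allow_mixed_modes:
        raise ValueError(f"mixed guide modes {sorted(modes)}; pass allow_mixed_modes=True")
    if len(set(seqs)) != len(seqs):
        warnings.warn("duplicate spacers in array", stacklevel=2)
    return CrisprArray(repeat, tuple(seqs), promoter_label)


def write_oligos_fasta(constructs: list[OligoConstruct], path) -> None:
    with open(path, "w") as fh:
        for c in constructs:
            fh.write(f">{c.guide_id}\n{c.oligo}\n")


def write_oligos_csv(constructs: list[OligoConstruct], path) -> None:
    """Vendor-style order sheet: id, sequence, length."""
    with open(path, "w") as fh:
        fh.write("id,sequence,length\n")
        for c in constructs:
            fh.write(f"{c.guide_id},{c.oligo},{c.length}\n")


def write_array_genbank(array: CrisprArray, path, name: str = "mini_crispr") -> None:
    """Annotated array: repeat/spacer features over the assembled sequence."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    rec = SeqRecord(Seq(array.assembled), id=name, name=name[:16])
    rec.annotations["molecule_type"] = "DNA"
    pos = 0
    r = len(array.repeat)
    for i, spacer in enumerate(array.spacers):
        rec.features.append(
            SeqFeature(FeatureLocation(pos, pos + r), type="repeat_region",
                       qualifiers={"note": [f"repeat_{i}"]})
        )
        pos += r
        rec.features.append(
            SeqFeature(FeatureLocation(pos, pos + len(spacer)), type="misc_feature",
                       qualifiers={"note": [f"spacer_{i + 1}"]})
        )
        pos += len(spacer)
    rec.features.append(
        SeqFeature(FeatureLocation(pos, pos + r), type="repeat_region",
                   qualifiers={"note": [f"repeat_{len(array.spacers)}"]})
    )
    SeqIO.write([rec], str(path), "genbank")
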