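"""PAM scanning, saturation enumeration, PFMs, and mismatch matching.

PAM orientation: the 3-nt core sits immediately 5' of the protospacer on the
protospacer-carrying strand; of the 5-nt upstream window only positions
-3..-1 are constrained (the -5/-4 positions are recorded but free).

All mismatch comparisons are substitution-only Hamming distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .genome_io import GenomeRecord, revcomp, subsequence

BASES = "ACGT"

DEFAULT_CORE = "TTA"
DEFAULT_PERMISSIVE = ("TTA", "CTA", "TCA", "TTG", "TTT")


@dataclass(frozen=True)
class PamModel:
    """Categorical PAM model: a core motif plus a permissive activity set."""

    core: str = DEFAULT_CORE
    permissive_set: tuple[str, ...] = DEFAULT_PERMISSIVE
    upstream_free: int = 2  # unconstrained positions -5, -4

    def __post_init__(self) -> None:
        motifs = (self.core, *self.permissive_set)
        for m in motifs:
            if len(m) != 3 or set(m) - set(BASES):
                raise ValueError(f"PAM motifs must be 3 nt over ACGT, got {m!r}")
        if self.core not in self.permissive_set:
            raise ValueError("core must be a member of the permissive set")

    def classify(self, motif: str) -> str:
        """'core' | 'permissive' | 'none' for a 3-nt flank motif."""
        if motif == self.core:
            return "core"
        if motif in self.permissive_set:
            return "permissive"
        return "none"


@dataclass(frozen=True)
class PamSite:
    """A PAM core occurrence and the adjacent protospacer window.

    ``pam_start`` is the forward-axis coordinate of the core's first base as
    read on the protospacer-carrying strand; ``protospacer_start`` is the
    forward-axis coordinate of the first protospacer base (immediately 3' of
    the core on that strand).
    """

    contig_id: str
    strand: str
    pam_start: int
    protospacer_start: int
    max_protospacer_len: int


def scan_pams(
    genome: GenomeRecord,
    model: PamModel | None = None,
    region: tuple[int, int] | None = None,
    strands: str = "both",
) -> list[PamSite]:
    """Locate every occurrence of the core motif on the requested strands.

    A site is reported when the core's forward-axis footprint lies within
    ``region`` (whole contig by default). Output is deterministically ordered
    by (strand, pam_start) with '+' first. On circular contigs cores spanning
    the origin are included.
    """
    model = model or PamModel()
    core = model.core
    k = len(core)
    n = len(genome)
    lo, hi = region if region is not None else (0, n)
    if not (0 <= lo <= hi <= n):
        raise ValueError(f"region [{lo}, {hi}) outside contig of length {n}")

    seq = genome.sequence
    search = seq + seq[: k - 1] if genome.topology == "circular" else seq
    sites: list[PamSite] = []

    def _hits(hay: str, needle: str) -> list[int]:
        out, i = [], hay.find(needle)
        while i != -1:
            out.append(i)
            i = hay.find(needle, i + 1)
        return out

    if strands in ("+", "both"):
        for f in _hits(search, core):
            if f >= n:
                continue
            if region is not None and not (lo <= f and f + k <= hi):
                continue
            avail = (n - k) if genome.topology == "circular" else n - (f + k)
            sites.append(PamSite(genome.contig_id, "+", f, f + k, max(avail, 0)))
    if strands in ("-", "both"):
        # core on the minus strand == revcomp(core) on the forward string
        for f in _hits(search, revcomp(core)):
            if f >= n:
                continue
            if region is not None and not (lo <= f and f + k <= hi):
                continue
            pam_start = f + k - 1  # first core base as read 5'->3' on minus
            avail = (n - k) if genome.topology == "circular" else f
            sites.append(
                PamSite(genome.contig_id, "-", pam_start, f - 1, max(avail, 0))
            )
    sites.sort(key=lambda s: (s.strand, s.pam_start))
    return sites


def protospacer_seq(genome: GenomeRecord, site: PamSite, length: int) -> str:
    """The ``length``-nt protospacer 3' of the core, read on the site strand."""
    if length > site.max_protospacer_len:
        raise ValueError(
            f"only {site.max_protospacer_len} nt available, requested {length}"
        )
    n = len(genome)
    if site.strand == "+":
        return subsequence(genome, site.protospacer_start, site.protospacer_start + length, "+")
    end = site.protospacer_start + 1
    start = end - length
    if start < 0:  # origin wrap on circular contigs
        start, end = start + n, end + n
    return subsequence(genome, start, end, "-")


def enumerate_pam_variants(template: str) -> list[str]:
    """All completions of the N positions of ``template``, lexicographic order.

    Returns exactly 4**(#N) motifs: 'NNN' -> 64, 'NNTTA' -> 16, 'TTA' -> ['TTA'].
    """
    if set(template) - set(BASES + "N"):
        raise ValueError(f"template must be over ACGTN, got {template!r}")
    n_pos = [i for i, b in enumerate(template) if b == "N"]
    out = []
    chars = list(template)
    for combo in itertools.product(BASES, repeat=len(n_pos)):
        for i, b in zip(n_pos, combo):
            chars[i] = b
        out.append("".join(chars))
    return out


@dataclass
class PFM:
    """Position frequency matrix: 4 x L base counts (rows A, C, G, T)."""

    counts: np.ndarray
    n_sequences: int

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("base\t" + "\t".join(str(j + 1) for j in range(self.length)) + "\n")
            for i, b in enumerate(BASES):
                fh.write(b + "\t" + "\t".join(str(c) for c in self.counts[i]) + "\n")


def build_pfm(flanks: list[str]) -> PFM:
    """Tally base counts per column from equal-length sequences.

    Every column of the result sums to ``len(flanks)``.
    """
    if not flanks:
        raise ValueError("need at least one sequence")
    L = len(flanks[0])
    if any(len(s) != L for s in flanks):
        raise ValueError("ragged sequence lengths")
    idx = {b: i for i, b in enumerate(BASES)}
    counts = np.zeros((4, L), dtype=np.int64)
    for s in flanks:
        for j, b in enumerate(s):
            if b not in idx:
                raise ValueError(f"illegal base {b!r}")
            counts[idx[b], j] += 1
    return PFM(counts, len(flanks))


@dataclass(frozen=True)
class MatchHit:
    """A (mis)match of a spacer against a target window.

    ``offset`` is the forward-axis 0-based start of the matched window;
    ``flank5`` is the 5 nt immediately 5' of the window on the match strand
    (shorter near a linear-contig edge).
    """

    target_id: str
    offset: int
    strand: str
    mismatches: int
    flank5: str

    @property
    def pam_core(self) -> str:
        """Last 3 nt of the 5' flank (the -3..-1 PAM positions)."""
        return self.flank5[-3:]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming_window_scan(target: str, query: str) -> np.ndarray:
    """Mismatch count of ``query`` against every window of ``target``.

    Returns an int array of length ``len(target) - len(query) + 1`` (empty if
    the query is longer than the target). O(len(target) * len(query)) with
    vectorized inner comparisons; no large intermediates.
    """
    t = _encode(target)
    q = _encode(query)
    n_win = len(t) - len(q) + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int32)
    mm = np.zeros(n_win, dtype=np.int32)
    for j in range(len(q)):
        mm += t[j : j + n_win] != q[j]
    return mm


def match_spacer(
    spacer: str,
    targets: list[GenomeRecord],
    max_mm: int = 0,
    model: PamModel | None = None,
) -> list[MatchHit]:
    """Find all windows on either strand of each target within ``max_mm``
    substitutions of ``spacer``, each annotated with its 5-nt 5' flank.

    Sorted by (mismatches, target_id, offset, strand).
    """
    if len(spacer) < 8:
        raise ValueError("spacer must be at least 8 nt")
    S = len(spacer)
    hits: list[MatchHit] = []
    for rec in targets:
        fwd = rec.sequence
        L = len(fwd)
        for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
            mm = hamming_window_scan(seq, spacer)
            for i in np.flatnonzero(mm <= max_mm):
                i = int(i)
                flank = seq[max(i - 5, 0) : i]
                if rec.topology == "circular" and i < 5:
                    flank = seq[i - 5 :] + flank if i > 0 else seq[-5:]
                offset = i if strand == "+" else L - i - S
                hits.append(MatchHit(rec.contig_id, offset, strand, int(mm[i]), flank))
    hits.sort(key=lambda h: (h.mismatches, h.target_id, h.offset, h.strand))
    return hits


def parse_crispr_array(
    seq: str, repeat: str, max_repeat_mm: int = 2
) -> list[str]:
    """Recover ordered spacers from a repeat-spacer array.

    Repeat occurrences are located by Hamming matching with at most
    ``max_repeat_mm`` substitutions, taken greedily left to right without
    overlap; n spacers imply n+1 repeats.
    """
    if not repeat:
        raise ValueError("repeat must be non-empty")
    mm = hamming_window_scan(seq, repeat)
    positions: list[int] = []
    last_end = -1
    for i in np.flatnonzero(mm <= max_repeat_mm):
        if i >= last_end:
            positions.append(int(i))
            last_end = int(i) + len(repeat)
    if len(positions) < 2:
        raise ValueError(
            f"not an array: found {len(positions)} repeat occurrence(s), need >= 2"
        )
    spacers = []
    for a, b in itertools.pairwise(positions):
        spacers.append(seq[a + len(repeat) : b])
    return spacers
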