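"""Guide design: repression tgRNAs and cleavage/editing crRNAs.

The functional switch is spacer length: <=26 nt complementarity gives
transcriptional repression (tgRNA), >=27 nt engages cleavage. Library design
places one 20-mer tgRNA per positional third (upstream/mid/downstream) of
each gene on the template strand, i.e. protospacer + PAM are read from the
gene's coding strand. Truncation keeps the PAM-proximal (5') end of the
spacer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .genome_io import GeneModel, GenomeRecord, subsequence
from .offtarget import OfftargetPolicy, find_offtargets
from .pam import PamModel, PamSite, protospacer_seq

logger = logging.getLogger(__name__)

MODE_REPRESSION = "repression"
MODE_CLEAVAGE = "cleavage"

DEFAULT_TRUNCATION_LENGTHS = (30, 25, 20, 15, 11)

# Type IIS recognition sites excluded from spacers (both orientations)
DEFAULT_EXCLUSION = ("GGTCTC", "GAGACC", "CGTCTC", "GAGACG")

BIN_NAMES_3 = ("upstream", "mid", "downstream")


def classify_mode(length: int, boundary: int = 26) -> str:
    """'repression' iff length <= boundary, else 'cleavage'."""
    if length < 8:
        raise ValueError("spacer length must be >= 8")
    return MODE_REPRESSION if length <= boundary else MODE_CLEAVAGE


@dataclass(frozen=True)
class DesignParams:
    repression_len: int = 20
    cleavage_len: int = 30  # E. coli editing preset uses 38
    mode_boundary: int = 26
    guides_per_gene: int = 3
    strand_mode: str = "template"  # template | nontemplate | both
    bins: int = 3
    specificity_policy: OfftargetPolicy | None = None
    specificity_max_mm: int = 1
    exclusion: tuple[str, ...] = DEFAULT_EXCLUSION
    max_homopolymer: int = 6
    arm_len: int = 600
    pam: PamModel = field(default_factory=PamModel)

    def __post_init__(self) -> None:
        if not (self.repression_len <= self.mode_boundary < self.cleavage_len):
            raise ValueError(
                "require repression_len <= mode_boundary < cleavage_len, got "
                f"{self.repression_len}/{self.mode_boundary}/{self.cleavage_len}"
            )
        if self.bins < 1:
            raise ValueError("bins must be >= 1")
        if self.strand_mode not in ("template", "nontemplate", "both"):
            raise ValueError(f"bad strand_mode {self.strand_mode!r}")


def bin_name(idx: int, bins: int) -> str:
    if bins == 3:
        return BIN_NAMES_3[idx]
    return f"bin{idx}"


@dataclass(frozen=True)
class GuideDesign:
    """A designed spacer (sequence identical to its protospacer, 5'->3')."""

    guide_id: str
    gene_id: str
    spacer: str
    length: int
    mode: str
    targeted_strand: str  # template | nontemplate
    bin: str
    pam_core: str
    site: PamSite | None
    offset_in_gene: float
    offtarget_summary: dict[int, int] | None = None

    @property
    def intended_locus(self) -> tuple[str, str, int] | None:
        """(contig, strand, forward-axis protospacer window start) of the
        on-target site — used to exclude it from off-target reports."""
        if self.site is None:
            return None
        if self.site.strand == "+":
            return (self.site.contig_id, "+", self.site.protospacer_start)
        return (
            self.site.contig_id,
            "-",
            self.site.protospacer_start - self.length + 1,
        )


def truncation_series(
    full_spacer: str,
    lengths: tuple[int, ...] = DEFAULT_TRUNCATION_LENGTHS,
    base: GuideDesign | None = None,
    boundary: int = 26,
) -> list[GuideDesign]:
    """PAM-proximal prefixes of ``full_spacer`` at the requested lengths.

    Shortening removes PAM-distal (3') bases so every variant keeps the seed
    and addresses the same PamSite. Modes assigned by :func:`classify_mode`.
    """
    if max(lengths) > len(full_spacer):
        raise ValueError(
            f"requested length {max(lengths)} exceeds full spacer ({len(full_spacer)} nt)"
        )
    out = []
    for L in lengths:
        mode = classify_mode(L, boundary)
        if base is not None:
            out.append(
                replace(
                    base,
                    guide_id=f"{base.guide_id}_L{L}",
                    spacer=full_spacer[:L],
                    length=L,
                    mode=mode,
                )
            )
        else:
            out.append(
                GuideDesign(
                    guide_id=f"trunc_L{L}",
                    gene_id="",
                    spacer=full_spacer[:L],
                    length=L,
                    mode=mode,
                    targeted_strand="template",
                    bin="",
                    pam_core="",
                    site=None,
                    offset_in_gene=0.0,
                )
            )
    return out


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def _spacer_passes(spacer: str, params: DesignParams) -> bool:
    if any(m in spacer for m in params.exclusion):
        return False
    if max_homopolymer_run(spacer) > params.max_homopolymer:
        return False
    return True


def _gene_candidate_sites(
    gene: GeneModel, genome: GenomeRecord, params: DesignParams, spacer_len: int
):
    """Core-PAM sites whose protospacer lies fully inside the gene body.

    Yields (pos_in_gene, site) where pos_in_gene is the protospacer start
    measured from the gene's 5' end on the targeted strand. Template
    targeting reads protospacer+PAM from the gene's coding strand.
    """
    core = params.pam.core
    k = len(core)
    n = len(genome)
    coding = subsequence(genome, gene.start, gene.end, gene.strand)

    want_template = params.strand_mode in ("template", "both")
    want_nontemplate = params.strand_mode in ("nontemplate", "both")

    def _find(seq: str, needle: str):
        i = seq.find(needle)
        while i != -1:
            yield i
            i = seq.find(needle, i + 1)

    out = []
    if want_template:
        # core on the coding strand at gene-index i, protospacer at i+k
        for i in _find(coding, core):
            pos = i + k
            if pos + spacer_len > len(coding):
                continue
            if gene.strand == "+":
                pam_start = (gene.start + i) % n
                ps_start = (gene.start + pos) % n
                avail = (n - k) if genome.topology == "circular" else n - (pam_start + k)
                site = PamSite(genome.contig_id, "+", pam_start, ps_start, avail)
            else:
                pam_start = (gene.end - 1 - i) % n
                ps_start = (gene.end - 1 - pos) % n
                avail = (n - k) if genome.topology == "circular" else ps_start + 1
                site = PamSite(genome.contig_id, "-", pam_start, ps_start, avail)
            out.append((pos, site, "template"))
    if want_nontemplate:
        from .genome_io import revcomp

        noncoding = revcomp(coding)
        gl = len(coding)
        for i in _find(noncoding, core):
            pos = i + k  # protospacer start, noncoding-strand coordinates
            if pos + spacer_len > gl:
                continue
            if gene.strand == "+":
                pam_start = (gene.end - 1 - i) % n
                ps_start = (gene.end - 1 - pos) % n
                avail = (n - k) if genome.topology == "circular" else ps_start + 1
                site = PamSite(genome.contig_id, "-", pam_start, ps_start, avail)
            else:
                pam_start = (gene.start + i) % n
                ps_start = (gene.start + pos) % n
                avail = (n - k) if genome.topology == "circular" else n - (pam_start + k)
                site = PamSite(genome.contig_id, "+", pam_start, ps_start, avail)
            # bin by the coding-axis coordinate of the protospacer's 5' base
            out.append((gl - 1 - pos, site, "nontemplate"))
    return out


def design_gene_guides(
    gene: GeneModel,
    genome: GenomeRecord,
    params: DesignParams | None = None,
    genomes_for_offtarget: list[GenomeRecord] | None = None,
) -> list[GuideDesign]:
    """Up to ``guides_per_gene`` tgRNAs for one gene, one per positional bin.

    The gene body is split into ``bins`` equal parts; within each bin the
    candidate closest to the bin center that passes the exclusion,
    homopolymer and (optional) specificity filters wins. Ties break on fewest
    off-target hits, then distance to center, then genome coordinate.
    """
    params = params or DesignParams()
    L = params.repression_len
    if len(gene) < L + len(params.pam.core):
        logger.warning("gene %s too short for design (%d nt)", gene.gene_id, len(gene))
        return []

    candidates = []
    for pos, site, tstrand in _gene_candidate_sites(gene, genome, params, L):
        spacer = protospacer_seq(genome, site, L)
        if not _spacer_passes(spacer, params):
            continue
        n_ot = 0
        summary = None
        if params.specificity_policy is not None:
            rep = find_offtargets(
                spacer,
                _intended_from_site(site, L, genome),
                genomes_for_offtarget or [genome],
                max_mm=params.specificity_max_mm,
                policy=params.specificity_policy,
                model=params.pam,
            )
            if not rep.passed:
                continue
            n_ot = rep.n_hits
            summary = rep.counts_by_mm
        candidates.append((pos, site, tstrand, spacer, n_ot, summary))

    gl = len(gene)
    guides: list[GuideDesign] = []
    for b in range(params.bins):
        lo = b * gl / params.bins
        hi = (b + 1) * gl / params.bins
        center = (lo + hi) / 2
        in_bin = [c for c in candidates if lo <= c[0] < hi]
        if not in_bin:
            logger.debug("gene %s: no candidate in bin %s", gene.gene_id, bin_name(b, params.bins))
            continue
        in_bin.sort(key=lambda c: (c[4], abs(c[0] - center), c[1].pam_start, c[1].strand))
        pos, site, tstrand, spacer, _, summary = in_bin[0]
        name = bin_name(b, params.bins)
        guides.append(
            GuideDesign(
                guide_id=f"{gene.gene_id}_{name}",
                gene_id=gene.gene_id,
                spacer=spacer,
                length=L,
                mode=classify_mode(L, params.mode_boundary),
                targeted_strand=tstrand,
                bin=name,
                pam_core=params.pam.core,
                site=site,
                offset_in_gene=pos / gl,
                offtarget_summary=summary,
            )
        )
        if len(guides) >= params.guides_per_gene:
            break
    return guides


def _intended_from_site(site: PamSite, length: int, genome: GenomeRecord):
    if site.strand == "+":
        return (site.contig_id, "+", site.protospacer_start)
    return (site.contig_id, "-", site.protospacer_start - length + 1)


@dataclass(frozen=True)
class LibraryStats:
    genes_total: int
    genes_targeted: int
    genes_with_full_bins: int
    total_guides: int

    @property
    def fraction_targeted(self) -> float:
        return self.genes_targeted / self.genes_total if self.genes_total else 0.0

    @property
    def fraction_full_bins(self) -> float:
        return self.genes_with_full_bins / self.genes_total if self.genes_total else 0.0


def design_library(
    genomes: list[GenomeRecord],
    genes: list[GeneModel],
    params: DesignParams | None = None,
) -> tuple[list[GuideDesign], LibraryStats]:
    """Genome-scale tgRNA library: design_gene_guides over every gene.

    Deterministic: same inputs give a byte-identical manifest. Stats report
    coverage (genes with >=1 guide) and full-bin coverage (one guide per bin).
    """
    params = params or DesignParams()
    by_contig = {g.contig_id: g for g in genomes}
    guides: list[GuideDesign] = []
    targeted = 0
    full = 0
    for gene in sorted(genes, key=lambda g: (g.contig_id, g.start, g.gene_id)):
        contig = by_contig.get(gene.contig_id)
        if contig is None:
            raise ValueError(f"gene {gene.gene_id} references unknown contig {gene.contig_id}")
        gg = design_gene_guides(gene, contig, params, genomes_for_offtarget=genomes)
        guides.extend(gg)
        if gg:
            targeted += 1
        if len(gg) == params.bins:
            full += 1
    stats = LibraryStats(len(genes), targeted, full, len(guides))
    return guides, stats


@dataclass(frozen=True)
class EditingDesign:
    """Cleavage guide + homology arms flanking a deletion interval."""

    guide: GuideDesign
    del_start: int
    del_end: int
    upstream_arm: str
    downstream_arm: str
    arm_len: int

    @property
    def arm_coords(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.del_start - self.arm_len, self.del_start),
            (self.del_end, self.del_end + self.arm_len),
        )


def design_editing(
    interval: tuple[int, int] | GeneModel,
    genome: GenomeRecord,
    params: DesignParams | None = None,
) -> EditingDesign:
    """Pick a cleavage-length spacer inside a deletion interval and homology
    arms immediately flanking it; verify the post-deletion locus is immune
    (no <=1-mismatch spacer match next to a permissive PAM).
    """
    params = params or DesignParams()
    if isinstance(interval, GeneModel):
        del_start, del_end = interval.start, interval.end
    else:
        del_start, del_end = interval
    n = len(genome)
    if not (0 <= del_start < del_end <= n):
        raise ValueError(f"deletion interval [{del_start}, {del_end}) outside contig")
    if del_start - params.arm_len < 0 or del_end + params.arm_len > n:
        if genome.topology != "circular":
            raise ValueError("arms extend past the ends of a linear contig")

    L = params.cleavage_len
    region_gene_fwd = GeneModel("_del", genome.contig_id, del_start, del_end, "+")
    region_gene_rev = GeneModel("_del", genome.contig_id, del_start, del_end, "-")
    p_both = replace(params, strand_mode="template")
    cands = _gene_candidate_sites(region_gene_fwd, genome, p_both, L)
    cands += _gene_candidate_sites(region_gene_rev, genome, p_both, L)

    center = (del_end - del_start) / 2
    cands.sort(key=lambda c: (abs(c[0] - center), c[1].pam_start, c[1].strand))

    from .pam import match_spacer

    edited = GenomeRecord(
        genome.contig_id + "_edited",
        genome.sequence[:del_start] + genome.sequence[del_end:],
        genome.topology,
    )
    errors = []
    for pos, site, _ in cands:
        spacer = protospacer_seq(genome, site, L)
        if not _spacer_passes(spacer, params):
            continue
        residual = [
            h
            for h in match_spacer(spacer, [edited], max_mm=1, model=params.pam)
            if params.pam.classify(h.pam_core) != "none" and len(h.flank5) >= 3
        ]
        if residual:
            errors.append(f"spacer at {site.pam_start} re-matches edited locus")
            continue
        guide = GuideDesign(
            guide_id=f"edit_{genome.contig_id}_{del_start}_{del_end}",
            gene_id=interval.gene_id if isinstance(interval, GeneModel) else "_interval",
            spacer=spacer,
            length=L,
            mode=classify_mode(L, params.mode_boundary),
            targeted_strand="template",
            bin="",
            pam_core=params.pam.core,
            site=site,
            offset_in_gene=pos / (del_end - del_start),
        )
        up_start = del_start - params.arm_len
        if up_start < 0:  # origin wrap (circular topology checked above)
            up_start += n
        up = subsequence(genome, up_start, up_start + params.arm_len, "+")
        down = subsequence(genome, del_end, del_end + params.arm_len, "+")
        return EditingDesign(guide, del_start, del_end, up, down, params.arm_len)

    nearby = _nearest_core_sites(genome, params, del_start, del_end)
    raise ValueError(
        f"no usable cleavage-mode site inside [{del_start}, {del_end}); "
        f"nearest core PAM sites outside: {nearby}"
        + (f"; rejected inside: {errors}" if errors else "")
    )


def _nearest_core_sites(genome, params, del_start, del_end, k: int = 3):
    from .pam import scan_pams

    sites = scan_pams(genome, params.pam)
    outside = [s for s in sites if not (del_start <= s.pam_start < del_end)]
    outside.sort(key=lambda s: min(abs(s.pam_start - del_start), abs(s.pam_start - del_end)))
    return [(s.strand, s.pam_start) for s in outside[:k]]


# ---------------------------------------------------------------------------
# manifest / export helpers

def guides_to_dataframe(guides: list[GuideDesign]) -> pd.DataFrame:
    rows = []
    for g in guides:
        rows.append(
            {
                "guide_id": g.guide_id,
                "gene_id": g.gene_id,
                "spacer": g.spacer,
                "length": g.length,
                "mode": g.mode,
                "targeted_strand": g.targeted_strand,
                "bin": g.bin,
                "contig": g.site.contig_id if g.site else "",
                # user-facing coordinates are 1-based inclusive
                "pam_start_1based": (g.site.pam_start + 1) if g.site else "",
                "strand": g.site.strand if g.site else "",
                "offtargets": (
                    ",".join(f"{k}:{v}" for k, v in sorted(g.offtarget_summary.items()))
                    if g.offtarget_summary
                    else ""
                ),
            }
        )
    return pd.DataFrame(rows)


def write_manifest(guides: list[GuideDesign], path) -> None:
    guides_to_dataframe(guides).to_csv(path, sep="\t", index=False)


def write_spacers_fasta(guides: list[GuideDesign], path) -> None:
    with open(path, "w") as fh:
        for g in guides:
            fh.write(f">{g.guide_id}\n{g.spacer}\n")


def guide_bed6(guides: list[GuideDesign]) -> list[tuple[str, int, int, str, int, str]]:
    """Protospacer loci as BED6 rows (0-based half-open)."""
    rows = []
    for g in guides:
        if g.site is None:
            continue
        loc = g.intended_locus
        rows.append((loc[0], loc[2], loc[2] + g.length, g.guide_id, 0, loc[1]))
    return rows
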