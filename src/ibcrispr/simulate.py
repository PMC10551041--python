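"""Synthetic fixtures: annotated micro-genomes with planted PAM sites and
spike-in screen FASTQs with per-read provenance.

Everything is fully determined by the spec seed. Truth tables are returned
as DataFrames (and written as TSV next to the generated files) so other
modules' tests can consume them; screen reads additionally carry their
source guide id in the FASTQ read id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DEFAULT_EXCLUSION, max_homopolymer_run
from .genome_io import GeneModel, GenomeRecord, revcomp, write_genbank

BASES = np.array(list("ACGT"))

DEFAULT_ANCHOR5 = "ACCTCGTTCAGGATAC"
DEFAULT_ANCHOR3 = "GTTCAC"


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for an annotated micro-genome with guaranteed PAM placement."""

    n_genes: int = 10
    gene_len_range: tuple[int, int] = (300, 1500)
    intergenic_len: int = 60
    gc_fraction: float = 0.5
    guaranteed_pams_per_bin: int = 1
    bins: int = 3
    spacer_len: int = 20
    pam_core: str = "TTA"
    topology: str = "linear"
    contig_id: str = "synth_1"
    seed: int = 0


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _valid_protospacer(rng: np.random.Generator, n: int, gc: float) -> str:
    """A random n-mer free of Type IIS sites and long homopolymers."""
    for _ in range(200):
        s = _random_seq(rng, n, gc)
        if any(m in s for m in DEFAULT_EXCLUSION):
            continue
        if max_homopolymer_run(s) > 6:
            continue
        return s
    raise RuntimeError("could not draw a valid protospacer")  # pragma: no cover


def make_genome(spec: GenomeSpec, out_dir: str | Path | None = None):
    """Build the genome described by ``spec``.

    Each gene carries >= ``guaranteed_pams_per_bin`` core-PAM sites per
    positional third on its coding strand (genes alternate between + and -).
    Returns (genome, genes, truth) where truth lists every planted site in
    the forward-axis PamSite convention; with ``out_dir`` also writes
    ``genome.gb`` and ``truth_pams.tsv``.
    """
    if spec.guaranteed_pams_per_bin < 1:
        raise ValueError("guaranteed_pams_per_bin must be >= 1")
    k = len(spec.pam_core)
    plant_len = k + spec.spacer_len
    min_bin = spec.guaranteed_pams_per_bin * (plant_len + 2)
    if spec.gene_len_range[0] // spec.bins < min_bin:
        raise ValueError(
            f"genes of {spec.gene_len_range[0]} nt cannot host "
            f"{spec.guaranteed_pams_per_bin} planted site(s) per bin"
        )

    rng = np.random.default_rng(spec.seed)
    chunks: list[str] = []
    genes: list[GeneModel] = []
    truth_rows = []
    pos = 0
    for gi in range(spec.n_genes):
        chunks.append(_random_seq(rng, spec.intergenic_len, spec.gc_fraction))
        pos += spec.intergenic_len
        glen = int(rng.integers(spec.gene_len_range[0], spec.gene_len_range[1] + 1))
        strand = "+" if gi % 2 == 0 else "-"
        gene_id = f"SYN_{gi + 1:04d}"

        coding = list("ATG" + _random_seq(rng, glen - 3, spec.gc_fraction))
        for b in range(spec.bins):
            lo = b * glen // spec.bins
            hi = (b + 1) * glen // spec.bins
            width = hi - lo
            for j in range(spec.guaranteed_pams_per_bin):
                # spread plants across the bin; protospacer start stays in-bin
                anchor = lo + (j + 1) * width // (spec.guaranteed_pams_per_bin + 1)
                p = min(max(anchor - k, lo), hi - plant_len, glen - plant_len)
                p = max(p, 3 if lo == 0 else lo)  # keep the ATG intact
                proto = _valid_protospacer(rng, spec.spacer_len, spec.gc_fraction)
                coding[p : p + plant_len] = spec.pam_core + proto
                if strand == "+":
                    site_strand, pam_start = "+", pos + p
                else:
                    site_strand, pam_start = "-", pos + glen - 1 - p
                truth_rows.append(
                    {
                        "gene_id": gene_id,
                        "contig_id": spec.contig_id,
                        "bin": b,
                        "strand": site_strand,
                        "pam_start": pam_start,
                        "protospacer": proto,
                    }
                )
        coding_str = "".join(coding)
        chunks.append(coding_str if strand == "+" else revcomp(coding_str))
        genes.append(GeneModel(gene_id, spec.contig_id, pos, pos + glen, strand))
        pos += glen
    chunks.append(_random_seq(rng, spec.intergenic_len, spec.gc_fraction))

    genome = GenomeRecord(spec.contig_id, "".join(chunks), spec.topology)
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_genbank([genome], genes, out_dir / "genome.gb")
        truth.to_csv(out_dir / "truth_pams.tsv", sep="\t", index=False)
    return genome, genes, truth


@dataclass(frozen=True)
class ScreenSpec:
    """Recipe for baseline/selected pooled-screen FASTQs with spike-ins."""

    library: tuple[tuple[str, str], ...]  # (guide_id, spacer) pairs
    depth: int = 1_000_000
    enriched: tuple[tuple[str, float], ...] = ()  # (guide_id, fold)
    error_rate: float = 0.0
    anchor5: str = DEFAULT_ANCHOR5
    anchor3: str = DEFAULT_ANCHOR3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if any(f < 0 for _, f in self.enriched):
            raise ValueError("fold-changes must be >= 0")
        ids = [g for g, _ in self.library]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate guide ids in library")
        unknown = {g for g, _ in self.enriched} - set(ids)
        if unknown:
            raise ValueError(f"enriched guides not in library: {sorted(unknown)}")
        if self.depth and self.depth < len(self.library):
            raise ValueError("depth must be >= library size")


def random_library(
    n: int, spacer_len: int = 20, seed: int = 0, prefix: str = "g"
) -> tuple[tuple[str, str], ...]:
    """A seeded library of unique random spacers (mutual Hamming > 1)."""
    rng = np.random.default_rng(seed)
    spacers: list[str] = []
    while len(spacers) < n:
        s = "".join(BASES[rng.integers(0, 4, size=spacer_len)])
        ok = True
        for t in spacers:
            if sum(a != b for a, b in zip(s, t)) <= 1:
                ok = False
                break
        if ok:
            spacers.append(s)
    width = len(str(n))
    return tuple((f"{prefix}{i + 1:0{width}d}", s) for i, s in enumerate(spacers))


def _mutate(read: str, rng: np.random.Generator, rate: float) -> str:
    k = rng.binomial(len(read), rate)
    if k == 0:
        return read
    chars = list(read)
    for j in rng.choice(len(read), size=k, replace=False):
        alts = [b for b in "ACGT" if b != chars[j]]
        chars[j] = alts[rng.integers(0, 3)]
    return "".join(chars)


def _write_sample(
    path: Path,
    spec: ScreenSpec,
    counts: np.ndarray,
    rng: np.random.Generator,
) -> None:
    with open(path, "w") as fh:
        for (gid, spacer), c in zip(spec.library, counts):
            read = spec.anchor5 + spacer + spec.anchor3
            for serial in range(int(c)):
                r = read if spec.error_rate == 0 else _mutate(read, rng, spec.error_rate)
                fh.write(f"@{gid}:{serial}\n{r}\n+\n{'I' * len(r)}\n")


def make_screen_reads(spec: ScreenSpec, out_dir: str | Path):
    """Draw baseline and selected samples by seeded multinomial sampling.

    Baseline abundances are uniform; in the selected sample each enriched
    guide's probability is multiplied by its fold-change. At error_rate 0,
    count_guides reproduces the truth counts exactly. Returns
    (baseline_fastq, selected_fastq, truth) with per-guide draw counts; read
    ids carry the source guide (per-read provenance).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    G = len(spec.library)
    fold = dict(spec.enriched)
    base_p = np.full(G, 1.0 / G)
    sel_w = np.array([fold.get(gid, 1.0) for gid, _ in spec.library])
    sel_p = base_p * sel_w
    sel_p = sel_p / sel_p.sum()

    base_counts = rng.multinomial(spec.depth, base_p) if spec.depth else np.zeros(G, int)
    sel_counts = rng.multinomial(spec.depth, sel_p) if spec.depth else np.zeros(G, int)

    baseline = out_dir / "baseline.fastq"
    selected = out_dir / "selected.fastq"
    _write_sample(baseline, spec, base_counts, rng)
    _write_sample(selected, spec, sel_counts, rng)

    truth = pd.DataFrame(
        {
            "guide_id": [g for g, _ in spec.library],
            "spacer": [s for _, s in spec.library],
            "fold": [fold.get(g, 1.0) for g, _ in spec.library],
            "baseline_count": base_counts,
            "selected_count": sel_counts,
        }
    )
    truth.to_csv(out_dir / "truth_counts.tsv", sep="\t", index=False)
    return baseline, selected, truth
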