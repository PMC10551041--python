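"""Pooled-screen quantification: anchored tgRNA counting and enrichment.

Read architecture: a fixed 5' anchor located with <=1 substitution, followed
by a fixed-length spacer window. Enrichment uses a per-guide two-sided exact
binomial test of the selected count against the baseline proportion with
BH-FDR correction; log2 fold changes are computed on CPM with a pseudocount.
A label-permutation alternative to the binomial test is exposed behind a
flag.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import revcomp

BASES = "ACGT"


class AmbiguousLibraryError(ValueError):
    """Two library spacers collide at the requested mismatch tolerance."""

    def __init__(self, collisions):
        self.collisions = collisions
        shown = "; ".join(f"{a} ~ {b}" for a, b in collisions[:5])
        super().__init__(
            f"{len(collisions)} spacer pair(s) within the mismatch tolerance: {shown}"
        )


@dataclass
class CountTable:
    """Per-guide read counts for one sample plus unassigned tallies."""

    counts: dict[str, int]
    unassigned: dict[str, int] = field(default_factory=dict)

    @property
    def total_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def total_unassigned(self) -> int:
        return sum(self.unassigned.values())

    @property
    def total_reads(self) -> int:
        return self.total_assigned + self.total_unassigned

    def cpm(self) -> dict[str, float]:
        t = self.total_assigned
        if t == 0:
            raise ValueError("zero assigned reads")
        return {g: 1e6 * c / t for g, c in self.counts.items()}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("guide_id\tcount\n")
            for g in sorted(self.counts):
                fh.write(f"{g}\t{self.counts[g]}\n")
            for reason in sorted(self.unassigned):
                fh.write(f"_unassigned:{reason}\t{self.unassigned[reason]}\n")


def _read_fastq_seqs(path: str | Path):
    """Yield read sequences from a (optionally gzipped) FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.strip().upper()


def _one_mismatch_neighbors(seq: str):
    for j, orig in enumerate(seq):
        for b in BASES:
            if b != orig:
                yield seq[:j] + b + seq[j + 1 :]


def check_library_unique(spacers: dict[str, str], max_mm: int) -> None:
    """Fail up front if two spacers are within ``max_mm`` of each other."""
    ids = sorted(spacers)
    if len({spacers[g] for g in ids}) != len(ids):
        seen: dict[str, str] = {}
        coll = []
        for g in ids:
            s = spacers[g]
            if s in seen:
                coll.append((seen[s], g))
            seen[s] = g
        raise AmbiguousLibraryError(coll)
    if max_mm >= 1:
        coll = []
        # pairwise Hamming check on equal-length spacers (libraries are small)
        by_len: dict[int, list[str]] = {}
        for g in ids:
            by_len.setdefault(len(spacers[g]), []).append(g)
        for glist in by_len.values():
            arr = np.array(
                [np.frombuffer(spacers[g].encode(), dtype=np.uint8) for g in glist]
            )
            for i in range(len(glist)):
                mm = (arr[i + 1 :] != arr[i]).sum(axis=1)
                for j in np.flatnonzero(mm <= max_mm):
                    coll.append((glist[i], glist[i + 1 + int(j)]))
        if coll:
            raise AmbiguousLibraryError(coll)


def _locate_anchor(read: str, anchor: str, max_mm: int = 1) -> int:
    """Start of the best anchor occurrence with <= max_mm substitutions, or -1."""
    n = len(read) - len(anchor) + 1
    best, best_i = max_mm + 1, -1
    for i in range(max(n, 0)):
        mm = sum(a != b for a, b in zip(read[i : i + len(anchor)], anchor))
        if mm < best:
            best, best_i = mm, i
            if mm == 0:
                break
    return best_i if best <= max_mm else -1


def count_guides(
    reads: str | Path,
    spacers: dict[str, str],
    anchor5: str,
    max_mm_spacer: int = 0,
    orient: str = "forward",
    anchor_mm: int = 1,
) -> CountTable:
    """Assign each read to at most one guide by anchored spacer extraction.

    The spacer window is the fixed-length stretch immediately 3' of the 5'
    anchor. ``max_mm_spacer`` is 0 or 1; the library must be unambiguous at
    that tolerance (checked up front). Unassigned reads are tallied with
    reason codes; assigned + unassigned == reads processed.
    """
    if max_mm_spacer not in (0, 1):
        raise ValueError("max_mm_spacer must be 0 or 1")
    if orient not in ("forward", "both"):
        raise ValueError("orient must be forward|both")
    check_library_unique(spacers, max_mm_spacer)
    lengths = {len(s) for s in spacers.values()}
    if len(lengths) != 1:
        raise ValueError("library spacers must share one length")
    (slen,) = lengths

    lookup: dict[str, str] = {s: g for g, s in spacers.items()}
    if max_mm_spacer == 1:
        for g, s in spacers.items():
            for nb in _one_mismatch_neighbors(s):
                lookup.setdefault(nb, g)
        # exact spacers always win over a neighbor of another guide
        for g, s in spacers.items():
            lookup[s] = g

    counts = {g: 0 for g in spacers}
    unassigned = {"no_anchor": 0, "too_short": 0, "no_spacer_match": 0}
    for read in _read_fastq_seqs(reads):
        candidates = [read] if orient == "forward" else [read, revcomp(read)]
        assigned = False
        reason = "no_anchor"
        for seq in candidates:
            i = _locate_anchor(seq, anchor5, anchor_mm)
            if i == -1:
                continue
            start = i + len(anchor5)
            window = seq[start : start + slen]
            if len(window) < slen:
                reason = "too_short"
                continue
            gid = lookup.get(window)
            if gid is None:
                reason = "no_spacer_match"
                continue
            counts[gid] += 1
            assigned = True
            break
        if not assigned:
            unassigned[reason] += 1
    return CountTable(counts, unassigned)


@dataclass(frozen=True)
class EnrichmentResult:
    guide_id: str
    baseline_count: int
    selected_count: int
    baseline_cpm: float
    selected_cpm: float
    log2fc: float
    p_value: float
    q_value: float
    rank: int


def _binom_p(k: int, n: int, p0: float) -> float:
    return stats.binomtest(k, n, p0, alternative="two-sided").pvalue


def enrich(
    baseline: CountTable,
    selected: CountTable,
    c: float = 0.5,
    alpha: float = 0.05,
    method: str = "binomial",
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Per-guide enrichment of ``selected`` over ``baseline``.

    p-values: two-sided exact binomial test of the selected count against the
    baseline proportion b_i/B (falling back to c/B when b_i == 0), or a
    seeded permutation test with ``method='permutation'``. BH-FDR q-values.
    Ordering: guides with q <= alpha first, each block sorted by descending
    log2fc, ties broken by guide_id; rank is 1-based over that order.
    """
    if set(baseline.counts) != set(selected.counts):
        raise ValueError("baseline and selected tables cover different guides")
    B = baseline.total_assigned
    S = selected.total_assigned
    if B == 0 or S == 0:
        raise ValueError("zero-total sample")
    guides = sorted(baseline.counts)
    b_cpm = baseline.cpm()
    s_cpm = selected.cpm()

    log2fc = {
        g: float(np.log2((s_cpm[g] + c) / (b_cpm[g] + c))) for g in guides
    }
    if method == "binomial":
        pvals = []
        for g in guides:
            b_i = baseline.counts[g]
            p0 = b_i / B if b_i > 0 else c / B
            pvals.append(_binom_p(selected.counts[g], S, p0))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        obs = np.array([log2fc[g] for g in guides])
        b_arr = np.array([baseline.counts[g] for g in guides], dtype=float)
        probs = b_arr / b_arr.sum()
        exceed = np.ones(len(guides))
        for _ in range(n_permutations):
            perm = rng.multinomial(S, probs)
            perm_cpm = 1e6 * perm / S
            perm_fc = np.log2((perm_cpm + c) / (np.array([b_cpm[g] for g in guides]) + c))
            exceed += np.abs(perm_fc) >= np.abs(obs)
        pvals = list(exceed / (n_permutations + 1))
    else:
        raise ValueError(f"unknown method {method!r}")

    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    sig = {g: q <= alpha for g, q in zip(guides, qvals)}
    order = sorted(
        guides,
        key=lambda g: (not sig[g], -log2fc[g], g),
    )
    rank_of = {g: i + 1 for i, g in enumerate(order)}
    results = [
        EnrichmentResult(
            guide_id=g,
            baseline_count=baseline.counts[g],
            selected_count=selected.counts[g],
            baseline_cpm=b_cpm[g],
            selected_cpm=s_cpm[g],
            log2fc=log2fc[g],
            p_value=p,
            q_value=q,
            rank=rank_of[g],
        )
        for g, p, q in zip(guides, pvals, qvals)
    ]
    results.sort(key=lambda r: r.rank)
    return results


def top_hits(
    results: list[EnrichmentResult],
    k: int,
    by_gene: dict[str, str] | None = None,
) -> list[str]:
    """First ``k`` guides in enrichment order (stable on guide_id ties).

    With ``by_gene`` (guide_id -> gene_id) hits are aggregated to genes by
    each gene's best-ranked guide.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(results, key=lambda r: r.rank)
    if by_gene is None:
        if k > len(ordered):
            import warnings

            warnings.warn(f"k={k} exceeds library size {len(ordered)}; truncating", stacklevel=2)
        return [r.guide_id for r in ordered[:k]]
    seen: list[str] = []
    for r in ordered:
        gene = by_gene.get(r.guide_id, r.guide_id)
        if gene not in seen:
            seen.append(gene)
        if len(seen) == k:
            break
    return seen


def results_to_dataframe(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def write_enrichment_tsv(results: list[EnrichmentResult], path) -> None:
    results_to_dataframe(results).to_csv(path, sep="\t", index=False)
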