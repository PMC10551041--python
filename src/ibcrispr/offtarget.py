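"""Genome-wide specificity search under the permissive PAM set.

Exhaustive substitution-only scan of both strands; the intended site is
excluded by coordinates (not by sequence), so perfect duplicates elsewhere
count as off-targets. Truncated guides are screened at their truncated
length. No seed-region weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import GenomeRecord
from .pam import MatchHit, PamModel, match_spacer


@dataclass(frozen=True)
class OfftargetPolicy:
    """Disqualify a guide when a secondary site has <= max_mm_reject
    mismatches and a flank core inside ``pam_scope``."""

    max_mm_reject: int = 1
    pam_scope: str = "permissive_set"  # "core_only" | "permissive_set"

    def __post_init__(self) -> None:
        if self.max_mm_reject < 0:
            raise ValueError("max_mm_reject must be >= 0")
        if self.pam_scope not in ("core_only", "permissive_set"):
            raise ValueError(f"unknown pam_scope {self.pam_scope!r}")


@dataclass
class OfftargetReport:
    guide_id: str
    hits: list[MatchHit]
    counts_by_mm: dict[int, int]
    passed: bool

    @property
    def n_hits(self) -> int:
        return len(self.hits)


def _pam_class(hit: MatchHit, model: PamModel) -> str:
    core = hit.pam_core
    if len(core) < 3:
        return "none"
    return model.classify(core)


def find_offtargets(
    spacer: str,
    intended: tuple[str, str, int] | None,
    genomes: list[GenomeRecord],
    max_mm: int = 3,
    policy: OfftargetPolicy | None = None,
    model: PamModel | None = None,
    guide_id: str = "",
) -> OfftargetReport:
    """Scan ``genomes`` for secondary matches of ``spacer``.

    ``intended`` identifies the on-target locus as (contig_id, strand,
    forward-axis window start) and is removed from the hit list. ``passed``
    is False when any remaining hit has mismatches <= policy.max_mm_reject
    and its flank core falls inside the policy's PAM scope.
    """
    policy = policy or OfftargetPolicy()
    model = model or PamModel()
    all_hits = match_spacer(spacer, genomes, max_mm=max_mm, model=model)
    hits = [
        h
        for h in all_hits
        if intended is None
        or (h.target_id, h.strand, h.offset) != tuple(intended)
    ]
    counts = {m: 0 for m in range(max_mm + 1)}
    for h in hits:
        counts[h.mismatches] += 1
    passed = True
    for h in hits:
        if h.mismatches > policy.max_mm_reject:
            continue
        klass = _pam_class(h, model)
        if policy.pam_scope == "core_only" and klass == "core":
            passed = False
            break
        if policy.pam_scope == "permissive_set" and klass in ("core", "permissive"):
            passed = False
            break
    return OfftargetReport(guide_id, hits, counts, passed)


def batch_specificity(
    guides,
    genomes: list[GenomeRecord],
    policy: OfftargetPolicy | None = None,
    max_mm: int = 3,
    model: PamModel | None = None,
) -> list[OfftargetReport]:
    """One report per guide; results identical to per-guide calls.

    ``guides`` is any iterable of objects exposing ``guide_id``, ``spacer``
    and ``intended_locus`` (see design.GuideDesign), or plain
    (guide_id, spacer, intended) triples.
    """
    reports = []
    for g in guides:
        if isinstance(g, tuple):
            gid, spacer, intended = g
        else:
            gid, spacer, intended = g.guide_id, g.spacer, g.intended_locus
        reports.append(
            find_offtargets(
                spacer, intended, genomes, max_mm=max_mm, policy=policy,
                model=model, guide_id=gid,
            )
        )
    return reports


def write_report_tsv(reports: list[OfftargetReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("guide_id\tn_hits\tcounts_by_mm\tpass\n")
        for r in reports:
            cm = ",".join(f"{k}:{v}" for k, v in sorted(r.counts_by_mm.items()))
            fh.write(f"{r.guide_id}\t{r.n_hits}\t{cm}\t{r.passed}\n")
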