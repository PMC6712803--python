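"""Read-backed cis/trans phasing of two nearby variants.

When two candidate compound-heterozygous variants lie within the span of
a sequencing fragment, each fragment that covers both loci reports one
haplotype. If fragments carry either alternate allele but never both,
the variants are in trans (compound heterozygous); if fragments carry
both alternates together and never singly, they are in cis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pysam

log = logging.getLogger(__name__)

REF, ALT = "ref", "alt"
Observation = Optional[str]  # REF, ALT or None (locus uncovered/uninformative)


def variant_span(start: int, end: int) -> int:
    """Length in bp of a variant printed in 1-based inclusive coordinates
    (the genome-browser convention): end - start + 1."""
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    return end - start + 1


@dataclass(frozen=True)
class VariantSite:
    """A variant locus, 0-based half-open internally.

    ``kind`` is "snv" (ref/alt are single bases) or "del" (the interval
    [start, end) is deleted on the alternate allele).
    """

    chrom: str
    start: int
    end: int
    kind: str
    ref: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("snv", "del"):
            raise ValueError("kind must be 'snv' or 'del'")
        if self.end <= self.start:
            raise ValueError("empty variant interval")
        if self.kind == "snv" and self.end - self.start != 1:
            raise ValueError("SNV must span exactly one base")

    @property
    def span(self) -> int:
        return self.end - self.start


_SNV_RE = re.compile(r"^([^:]+):(\d+):([ACGT]):([ACGT])$")
_DEL_RE = re.compile(r"^([^:]+):(\d+)-(\d+):DEL$", re.IGNORECASE)


def parse_variant(spec: str) -> VariantSite:
    """Parse ``chrom:pos:REF:ALT`` (SNV) or ``chrom:start-end:DEL``.

    Positions are 1-based inclusive, as printed by genome browsers.
    """
    m = _SNV_RE.match(spec)
    if m:
        chrom, pos, ref, alt = m.groups()
        p = int(pos) - 1
        return VariantSite(chrom, p, p + 1, "snv", ref, alt)
    m = _DEL_RE.match(spec)
    if m:
        chrom, s, e = m.groups()
        return VariantSite(chrom, int(s) - 1, int(e), "del")
    raise ValueError(f"cannot parse variant spec {spec!r}")


VERDICTS = ("trans", "cis", "ambiguous")


@dataclass(frozen=True)
class PhaseCall:
    """Fragment tallies over the two loci and the resulting verdict."""

    n_A_only: int
    n_B_only: int
    n_both: int
    n_neither: int
    verdict: str

    @property
    def n_informative(self) -> int:
        return self.n_A_only + self.n_B_only + self.n_both + self.n_neither


def call_phase(
    observations: Iterable[tuple[Observation, Observation]],
    min_fragments: int = 3,
) -> PhaseCall:
    """Decide cis/trans from per-fragment allele observations.

    Each observation is (allele at A, allele at B) for one fragment;
    fragments not covering both loci (None at either) are uninformative.
    Verdict: trans iff >= min_fragments carry A-only and >= min_fragments
    carry B-only with ZERO dual-variant fragments; cis is the mirror case;
    otherwise ambiguous. The strict zero on the opposing class is the
    point: the compound-heterozygosity claim rests on the absence of
    fragments bearing both variants.
    """
    n_a = n_b = n_both = n_neither = 0
    for obs_a, obs_b in observations:
        if obs_a is None or obs_b is None:
            continue
        if obs_a == ALT and obs_b == ALT:
            n_both += 1
        elif obs_a == ALT:
            n_a += 1
        elif obs_b == ALT:
            n_b += 1
        else:
            n_neither += 1
    if n_a + n_b + n_both + n_neither == 0:
        log.warning("no informative fragments; verdict ambiguous")
        verdict = "ambiguous"
    elif n_a >= min_fragments and n_b >= min_fragments and n_both == 0:
        verdict = "trans"
    elif n_both >= min_fragments and n_a == 0 and n_b == 0:
        verdict = "cis"
    else:
        verdict = "ambiguous"
    return PhaseCall(n_a, n_b, n_both, n_neither, verdict)


def _observe_snv(read: pysam.AlignedSegment, site: VariantSite) -> Observation:
    if read.reference_start is None:
        return None
    for qpos, rpos in read.get_aligned_pairs():
        if rpos == site.start:
            if qpos is None:
                return None  # deletion over the SNV locus: no base observed
            base = read.query_sequence[qpos].upper()
            if base == site.alt:
                return ALT
            if base == site.ref:
                return REF
            return None
    return None


def _observe_deletion(read: pysam.AlignedSegment, site: VariantSite) -> Observation:
    """ALT if the alignment shows a deletion covering the interval, REF if
    it aligns across the interval without one, None otherwise."""
    if read.reference_start is None or read.cigartuples is None:
        return None
    if read.reference_start > site.start - 1 or read.reference_end < site.end + 1:
        return None  # must anchor on both sides to be informative
    rpos = read.reference_start
    deleted: set[int] = set()
    aligned: set[int] = set()
    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # M/=/X
            aligned.update(range(rpos, rpos + length))
            rpos += length
        elif op == 2:  # D
            deleted.update(range(rpos, rpos + length))
            rpos += length
        elif op == 3:  # N
            rpos += length
    target = set(range(site.start, site.end))
    if target <= deleted:
        return ALT
    if target <= aligned:
        return REF
    return None


def classify_fragments_sam(
    sam_path: str | Path, var_a: VariantSite, var_b: VariantSite
) -> dict[str, tuple[Observation, Observation]]:
    """Per-fragment (query name) allele observations at the two loci.

    A fragment's observation at a locus comes from whichever mate covers
    it; mates disagreeing at a locus make it uninformative there.
    """
    if var_a.chrom != var_b.chrom:
        raise ValueError("both variants must be on one chromosome")
    obs: dict[str, list[Observation]] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != var_a.chrom:
                continue
            o_a = (
                _observe_snv(read, var_a)
                if var_a.kind == "snv"
                else _observe_deletion(read, var_a)
            )
            o_b = (
                _observe_snv(read, var_b)
                if var_b.kind == "snv"
                else _observe_deletion(read, var_b)
            )
            cur = obs.setdefault(read.query_name, [None, None])
            for i, o in enumerate((o_a, o_b)):
                if o is None:
                    continue
                if cur[i] is None:
                    cur[i] = o
                elif cur[i] != o:
                    cur[i] = "conflict"
    return {
        name: (
            a if a in (REF, ALT) else None,
            b if b in (REF, ALT) else None,
        )
        for name, (a, b) in obs.items()
    }


def phase_two_variants(
    sam_path: str | Path,
    var_a: VariantSite,
    var_b: VariantSite,
    min_fragments: int = 3,
) -> PhaseCall:
    """Phase two variants from a SAM/BAM file of aligned read pairs."""
    fragments = classify_fragments_sam(sam_path, var_a, var_b)
    return call_phase(fragments.values(), min_fragments=min_fragments)


def write_phase_tsv(call: PhaseCall, var_a: VariantSite, var_b: VariantSite, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write(
            "var_a\tvar_b\tdistance_bp\tn_A_only\tn_B_only\tn_both\tn_neither\tverdict\n"
        )
        distance = max(var_b.start - var_a.end, var_a.start - var_b.end, 0)
        out.write(
            f"{var_a.chrom}:{var_a.start + 1}-{var_a.end}\t"
            f"{var_b.chrom}:{var_b.start + 1}-{var_b.end}\t{distance}\t"
            f"{call.n_A_only}\t{call.n_B_only}\t{call.n_both}\t{call.n_neither}\t"
            f"{call.verdict}\n"
        )
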