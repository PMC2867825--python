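"""In-silico model of the tag library chemistry.

A tag-profiling library anchors every cDNA fragment at a DpnII restriction
site (5'-GATC-3'); a type IIS enzyme (MmeI) then releases a fixed-length
20 bp fragment starting at that site.  Because the digestion of cDNA is
partial, a single transcript yields one tag per DpnII site, with the
3'-most site (closest to the poly(A) tail captured on oligo(dT) beads)
producing the dominant, *canonical* tag.

This module is purely deterministic sequence arithmetic: locate the sites,
derive the 20-mers, and rank them from the 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass

DPNII_MOTIF = "GATC"
TAG_LENGTH = 20

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class TagSite:
    """A usable DpnII site in a transcript and its released 20-mer.

    Attributes
    ----------
    offset : int
        0-based position of the G of GATC in the transcript (5'->3').
    sequence : str
        The 20-mer tag, starting with GATC.
    rank : int
        Index counted from the 3'-most usable site; rank 0 is the
        canonical tag.
    """

    offset: int
    sequence: str
    rank: int

    def __post_init__(self) -> None:
        if len(self.sequence) != TAG_LENGTH:
            raise ValueError(
                f"tag sequence must be {TAG_LENGTH} nt, got {len(self.sequence)}"
            )
        if not self.sequence.startswith(DPNII_MOTIF):
            raise ValueError(f"tag must start with {DPNII_MOTIF}: {self.sequence}")


def validate_transcript(seq: str) -> None:
    """Reject empty transcripts or transcripts with ambiguity codes."""
    if not seq:
        raise ValueError("transcript sequence is empty")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"transcript contains non-ACGT symbols: {sorted(bad)}")


def find_dpnii_sites(seq: str) -> list[int]:
    """Ascending 0-based offsets of every GATC occurrence in ``seq``.

    The motif cannot overlap itself, so a plain scan suffices.
    """
    validate_transcript(seq)
    sites: list[int] = []
    pos = seq.find(DPNII_MOTIF)
    while pos != -1:
        sites.append(pos)
        pos = seq.find(DPNII_MOTIF, pos + 1)
    return sites


def enumerate_tags(seq: str) -> list[TagSite]:
    """All usable tags of a transcript, ranked from the 3' end.

    A site is usable when the full 20-mer fits inside the transcript,
    i.e. the site has at least 16 bases downstream of its GATC; shorter
    fragments are assumed lost during size selection.  Ranks run
    0, 1, 2, ... from the 3'-most usable site toward 5'; the rank-0 tag
    is the canonical tag.  Returns ``[]`` when no site is usable.
    """
    usable = [p for p in find_dpnii_sites(seq) if p + TAG_LENGTH <= len(seq)]
    n = len(usable)
    return [
        TagSite(offset=p, sequence=seq[p : p + TAG_LENGTH], rank=n - 1 - i)
        for i, p in enumerate(usable)
    ]


def canonical_tag(seq: str) -> TagSite | None:
    """The rank-0 (3'-most usable) tag of a transcript, or None."""
    tags = enumerate_tags(seq)
    if not tags:
        return None
    return tags[-1]
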