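"""In-silico restriction digestion and gel band-pattern matching.

Class I amplicons digested with HinfI (recognition GANTC, cut after the G)
give haplotype-specific fragment patterns on a polyacrylamide gel; lines
carrying the same S haplotype share a pattern.  The gel model is
deliberately simple: fragments below a detection floor run off the gel,
and fragments closer in size than the gel's relative resolution co-migrate
into one band.  Fragment lengths are double-stranded sizes; the 3-nt 5'
overhang HinfI leaves does not affect gel mobility and is ignored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from ._iupac import IUPAC_SETS, validate_acgt, validate_iupac

__all__ = [
    "RestrictionEnzyme",
    "FragmentSet",
    "GelProfile",
    "HINFI",
    "find_sites",
    "digest",
    "gel_profile",
    "profiles_equal",
    "profile_table",
    "load_enzymes",
    "render_gel",
]

DEFAULT_RESOLUTION_PCT = 2.0   # 6% PAGE with silver staining resolves ~2%
DEFAULT_MIN_DETECT = 50        # smaller fragments run off the gel


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition: str  # IUPAC pattern
    cut_offset: int   # top-strand cut position within the window; 0 = before first base

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("empty recognition sequence")
        validate_iupac(self.recognition, f"enzyme {self.name}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside recognition window"
            )


#: HinfI: G^ANTC, palindromic (GANTC is its own reverse complement).
HINFI = RestrictionEnzyme("HinfI", "GANTC", 1)


@dataclass(frozen=True)
class FragmentSet:
    source_id: str
    fragment_lengths: tuple[int, ...]  # 5'->3' along the top strand

    def __post_init__(self) -> None:
        if any(length < 1 for length in self.fragment_lengths):
            raise ValueError("fragment of length < 1")

    @property
    def total_length(self) -> int:
        return sum(self.fragment_lengths)


@dataclass(frozen=True)
class GelProfile:
    bands: tuple[int, ...]  # strictly descending
    resolution_pct: float
    min_detect: int

    def __post_init__(self) -> None:
        if any(b2 >= b1 for b1, b2 in zip(self.bands, self.bands[1:])):
            raise ValueError("bands must be strictly descending")


def find_sites(sequence: str, enzyme: RestrictionEnzyme = HINFI) -> list[int]:
    """Top-strand cut positions of an enzyme on a sequence, ascending.

    For a palindromic recognition site a single-strand scan finds every
    site.  Cut positions in the open interval (0, len) only: a site whose
    cut falls on a sequence boundary produces no new fragment.
    """
    validate_acgt(sequence)
    pattern = enzyme.recognition
    m = len(pattern)
    cuts = []
    for offset in range(len(sequence) - m + 1):
        window = sequence[offset : offset + m]
        if all(base in IUPAC_SETS[p] for p, base in zip(pattern, window)):
            cut = offset + enzyme.cut_offset
            if 0 < cut < len(sequence):
                cuts.append(cut)
    return sorted(set(cuts))


def digest(
    sequence: str, enzyme: RestrictionEnzyme = HINFI, source_id: str = ""
) -> FragmentSet:
    """Complete digestion: fragments between successive cut positions."""
    cuts = find_sites(sequence, enzyme)
    bounds = [0, *cuts, len(sequence)]
    lengths = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return FragmentSet(source_id, lengths)


def gel_profile(
    fragments: FragmentSet,
    resolution_pct: float = DEFAULT_RESOLUTION_PCT,
    min_detect: int = DEFAULT_MIN_DETECT,
) -> GelProfile:
    """Resolution-limited band pattern of a fragment set.

    Fragments shorter than ``min_detect`` are dropped; the rest are sorted
    descending and greedily merged: a fragment within ``resolution_pct``
    of the current band's length joins that band (the band keeps the
    longest member's length).
    """
    if resolution_pct < 0:
        raise ValueError("resolution_pct must be >= 0")
    if min_detect < 1:
        raise ValueError("min_detect must be >= 1")
    visible = sorted(
        (f for f in fragments.fragment_lengths if f >= min_detect), reverse=True
    )
    bands: list[int] = []
    for frag in visible:
        if bands and (bands[-1] - frag) <= bands[-1] * resolution_pct / 100.0:
            continue  # co-migrates with the current band
        bands.append(frag)
    return GelProfile(tuple(bands), resolution_pct, min_detect)


def profiles_equal(a: GelProfile, b: GelProfile) -> bool:
    """Would two band patterns look identical on the same gel?

    True iff band counts match and each corresponding band pair differs
    by at most the gel resolution (relative to the larger band).
    """
    if (a.resolution_pct, a.min_detect) != (b.resolution_pct, b.min_detect):
        raise ValueError("profiles compared under different gel settings")
    if len(a.bands) != len(b.bands):
        return False
    tol = a.resolution_pct / 100.0
    return all(
        abs(x - y) <= max(x, y) * tol for x, y in zip(a.bands, b.bands)
    )


def profile_table(
    panel: Sequence[tuple[str, str]],
    enzyme: RestrictionEnzyme = HINFI,
    resolution_pct: float = DEFAULT_RESOLUTION_PCT,
    min_detect: int = DEFAULT_MIN_DETECT,
) -> tuple[int, dict[str, int]]:
    """Digest a panel of (genotype_id, amplicon sequence) and group profiles.

    Band-pattern equality at a finite gel resolution is not transitive, so
    genotypes are clustered by single linkage over the pairwise equality
    relation; cluster ids are numbered by first appearance in the panel
    (1-based).  Returns (distinct profile count, genotype -> profile id).
    """
    ids = [genotype_id for genotype_id, _ in panel]
    profiles = [
        gel_profile(digest(seq, enzyme, genotype_id), resolution_pct, min_detect)
        for genotype_id, seq in panel
    ]
    n = len(panel)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if profiles_equal(profiles[i], profiles[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    profile_ids: dict[str, int] = {}
    cluster_id: dict[int, int] = {}
    for i in range(n):
        root = find(i)
        if root not in cluster_id:
            cluster_id[root] = len(cluster_id) + 1
        profile_ids[ids[i]] = cluster_id[root]
    return len(cluster_id), profile_ids


def load_enzymes(path: str | Path) -> dict[str, RestrictionEnzyme]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        return {
            row["name"]: RestrictionEnzyme(
                row["name"], row["recognition"].upper(), int(row["cut_offset"])
            )
            for row in csv.DictReader(fh, delimiter="\t")
        }


def render_gel(
    profiles: dict[str, GelProfile], width: int = 60, max_len: int | None = None
) -> str:
    """Text-art rendering of band patterns, one lane per genotype."""
    if not profiles:
        return "(empty gel)\n"
    if max_len is None:
        max_len = max((b for p in profiles.values() for b in p.bands), default=1)
    lines = []
    label_w = max(len(k) for k in profiles)
    for genotype_id, profile in profiles.items():
        lane = [" "] * width
        for band in profile.bands:
            pos = min(width - 1, int(width * (1 - band / (max_len + 1))))
            lane[pos] = "|"
        lines.append(f"{genotype_id:>{label_w}} {''.join(lane)}")
    return "\n".join(lines) + "\n"
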