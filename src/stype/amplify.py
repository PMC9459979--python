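"""Virtual PCR with degenerate primers and Class I / Class II calling.

Radish S haplotypes fall into two sequence classes with distinct
self-incompatibility strength.  Each class has its own degenerate primer
pair targeting the SRK kinase domain (Class I: KD(I)-F/R, ~1200 bp product;
Class II: KD4/KD7, ~1000 bp product).  Running both pairs against a
genotype's DNA classifies it: a product from one pair only means a
homozygous-class genotype, products from both mean a Class I/II
heterozygote.

Coordinates are 0-based half-open on the top strand throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

from ._iupac import IUPAC_SETS, revcomp, validate_acgt, validate_iupac

__all__ = [
    "SIClass",
    "Role",
    "DegeneratePrimer",
    "PrimerPair",
    "Amplicon",
    "ClassCall",
    "iupac_match",
    "find_binding_sites",
    "virtual_pcr",
    "call_class",
    "load_primers",
    "default_primer_pairs",
    "size_window",
]

# Band sizes on the gel are approximate; accept expected length +/- 20%.
SIZE_WINDOW_FRACTION = 0.20


class SIClass(str, Enum):
    CLASS_I = "class_I"
    CLASS_II = "class_II"
    CLASS_I_II = "class_I_II"
    NONE = "none"


class Role(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class DegeneratePrimer:
    name: str
    sequence: str  # IUPAC alphabet, written 5'->3'
    si_class: SIClass
    role: Role

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"primer {self.name}: empty sequence")
        validate_iupac(self.sequence, f"primer {self.name}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    expected_length: int
    si_class: SIClass

    def __post_init__(self) -> None:
        if self.forward.role is not Role.FORWARD or self.reverse.role is not Role.REVERSE:
            raise ValueError("primer roles do not match pair slots")
        if self.expected_length <= 0:
            raise ValueError("expected_length must be positive")

    @property
    def name(self) -> str:
        return f"{self.forward.name}/{self.reverse.name}"


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int  # 0-based inclusive, top strand
    end: int    # 0-based exclusive
    pair_name: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ClassCall:
    genotype_id: str
    call: SIClass


def iupac_match(primer_window: str, target_window: str, max_mismatch: int = 0) -> bool:
    """Does an ACGT window satisfy a degenerate primer window?

    A position mismatches when the target base is outside the primer
    symbol's allowed base set; at most ``max_mismatch`` such positions are
    tolerated.
    """
    if len(primer_window) != len(target_window):
        raise ValueError(
            f"length mismatch: primer {len(primer_window)} vs target {len(target_window)}"
        )
    validate_iupac(primer_window, "primer window")
    validate_acgt(target_window, "target window")
    mismatches = 0
    for p, t in zip(primer_window, target_window):
        if t not in IUPAC_SETS[p]:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def _mismatch_positions(primer_window: str, target_window: str) -> list[int]:
    return [
        i for i, (p, t) in enumerate(zip(primer_window, target_window))
        if t not in IUPAC_SETS[p]
    ]


def find_binding_sites(
    primer: DegeneratePrimer, template: str, max_mismatch: int = 0
) -> list[tuple[int, str]]:
    """All binding sites of a primer on a template, as (offset, strand).

    Forward primers are matched on the top strand as written.  Reverse
    primers anneal to the top strand, so the top strand must contain the
    primer's reverse complement; those sites are reported with strand
    "bottom".  Offsets are 0-based positions of the matched window on the
    top strand, ascending.

    With ``max_mismatch > 0`` the three bases at the primer's 3' end must
    still match exactly — polymerase extension needs a paired 3' terminus.
    """
    validate_acgt(template, "template")
    if primer.role is Role.FORWARD:
        pattern, strand = primer.sequence, "top"
        # primer 3' end = rightmost pattern positions
        terminal = set(range(len(pattern) - 3, len(pattern)))
    else:
        pattern, strand = revcomp(primer.sequence), "bottom"
        # reverse complementing puts the primer 3' end leftmost
        terminal = set(range(0, 3))
    n, m = len(template), len(pattern)
    sites: list[tuple[int, str]] = []
    for offset in range(n - m + 1):
        window = template[offset : offset + m]
        bad = _mismatch_positions(pattern, window)
        if len(bad) <= max_mismatch and not (max_mismatch > 0 and terminal & set(bad)):
            sites.append((offset, strand))
    return sites


def size_window(pair: PrimerPair, fraction: float = SIZE_WINDOW_FRACTION) -> tuple[int, int]:
    """Acceptable product-length window around the pair's expected length."""
    lo = int(round(pair.expected_length * (1 - fraction)))
    hi = int(round(pair.expected_length * (1 + fraction)))
    return lo, hi


def virtual_pcr(
    template_id: str,
    template: str,
    pair: PrimerPair,
    window: tuple[int, int] | None = None,
    max_mismatch: int = 0,
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on a template.

    Every (forward site, reverse site) combination whose product length
    falls inside the size window yields one amplicon spanning the forward
    primer's first base through the reverse primer's binding window
    (inclusive of both primers).  Overlapping primer placements — where
    the two annealed primers would collide — are physically unamplifiable
    and discarded.
    """
    if window is None:
        window = size_window(pair)
    lo, hi = window
    if lo > hi:
        raise ValueError(f"size window min {lo} > max {hi}")
    fwd_sites = find_binding_sites(pair.forward, template, max_mismatch)
    rev_sites = find_binding_sites(pair.reverse, template, max_mismatch)
    min_len = len(pair.forward) + len(pair.reverse)
    amplicons = []
    for f, _ in fwd_sites:
        for r0, _ in rev_sites:
            end = r0 + len(pair.reverse)
            length = end - f
            if length <= min_len:  # colliding primers
                continue
            if lo <= length <= hi:
                amplicons.append(Amplicon(template_id, f, end, pair.name))
    amplicons.sort(key=lambda a: (a.start, a.end))
    return amplicons


def call_class(
    genotype_id: str,
    class_I_products: Sequence[Amplicon],
    class_II_products: Sequence[Amplicon],
) -> ClassCall:
    """Classify a genotype from which primer pairs amplified."""
    if class_I_products and class_II_products:
        call = SIClass.CLASS_I_II
    elif class_I_products:
        call = SIClass.CLASS_I
    elif class_II_products:
        call = SIClass.CLASS_II
    else:
        call = SIClass.NONE
    return ClassCall(genotype_id, call)


def load_primers(path: str | Path) -> dict[SIClass, PrimerPair]:
    """Load primer pairs from a TSV (name, si_class, role, sequence, expected_length)."""
    primers: dict[tuple[SIClass, Role], DegeneratePrimer] = {}
    lengths: dict[SIClass, int] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            si_class = SIClass(row["si_class"])
            role = Role(row["role"])
            primers[(si_class, role)] = DegeneratePrimer(
                row["name"], row["sequence"].upper(), si_class, role
            )
            lengths[si_class] = int(row["expected_length"])
    pairs = {}
    for si_class, expected in lengths.items():
        try:
            fwd = primers[(si_class, Role.FORWARD)]
            rev = primers[(si_class, Role.REVERSE)]
        except KeyError as exc:
            raise ValueError(f"{path}: incomplete pair for {si_class.value}") from exc
        pairs[si_class] = PrimerPair(fwd, rev, expected, si_class)
    return pairs


def default_primer_pairs() -> dict[SIClass, PrimerPair]:
    """The packaged radish SRK kinase-domain primer pairs."""
    return load_primers(Path(__file__).parent / "data" / "primers.tsv")
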