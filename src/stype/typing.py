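"""Identity-based S-haplotype assignment of SRK kinase-domain sequences.

A query kinase-domain sequence is compared to every reference haplotype by
global alignment with free terminal gaps; the best hit at or above the
same-haplotype identity threshold names the query, and a query below the
threshold against every reference is a candidate novel haplotype.  The
default threshold of 98.5% sits just below the smallest published
within-haplotype similarity between the teams' alleles (98.7%), while
distinct haplotypes diverge far more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional, Sequence

import pandas as pd
from Bio import Align

from .registry import Registry

__all__ = [
    "CallStatus",
    "ReferenceHaplotype",
    "HaplotypeCall",
    "FrequencyTable",
    "percent_identity",
    "assign_haplotype",
    "register_novel_call",
    "tally_frequencies",
    "heterozygote_resolve",
    "DEFAULT_IDENTITY_THRESHOLD",
    "AMBIGUITY_MARGIN_PCT",
]

DEFAULT_IDENTITY_THRESHOLD = 98.5
#: Two best hits from different unified haplotypes within this margin
#: (percentage points) make the call ambiguous rather than known.
AMBIGUITY_MARGIN_PCT = 0.1

# Alignment scoring is fixed and recorded here: match +1, mismatch -1,
# gap -2, terminal gaps free.
ALIGNMENT_SCORING = {
    "match": 1, "mismatch": -1, "gap_open": -2, "gap_extend": -2,
    "terminal_gaps": "free",
}


class CallStatus(str, Enum):
    KNOWN = "known"
    NOVEL = "novel"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ReferenceHaplotype:
    nau_name: str
    si_class: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.nau_name}: empty sequence")


@dataclass
class HaplotypeCall:
    query_id: str
    best_hit: Optional[str]
    identity_pct: float
    status: CallStatus
    assigned_name: Optional[str] = None  # set when a novel call is registered

    @property
    def resolved_name(self) -> str:
        """The NAU-S name this call resolves to; error while unresolved."""
        if self.status is CallStatus.KNOWN:
            assert self.best_hit is not None
            return self.best_hit
        if self.status is CallStatus.NOVEL and self.assigned_name is not None:
            return self.assigned_name
        raise ValueError(f"call for {self.query_id} is unresolved ({self.status.value})")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = ALIGNMENT_SCORING["match"]
    aligner.mismatch_score = ALIGNMENT_SCORING["mismatch"]
    aligner.open_gap_score = ALIGNMENT_SCORING["gap_open"]
    aligner.extend_gap_score = ALIGNMENT_SCORING["gap_extend"]
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


def percent_identity(a: str, b: str) -> float:
    """Global-alignment identity between two nucleotide sequences.

    Identity is matches over aligned columns, terminal-gap columns
    excluded, as a percentage.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("percent_identity requires non-empty sequences")
    alignment = _ALIGNER.align(a.upper(), b.upper())[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    if columns == 0:
        return 0.0
    return 100.0 * counts.identities / columns


def assign_haplotype(
    query_id: str,
    query_sequence: str,
    panel: Sequence[ReferenceHaplotype],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    registry: Optional[Registry] = None,
) -> HaplotypeCall:
    """Type one query against the reference panel.

    known: the best hit reaches the threshold (and no reference of a
    different unified haplotype ties it within the ambiguity margin);
    novel: every reference falls below the threshold; ambiguous: two
    references from different haplotypes tie at the top.
    """
    if not panel:
        raise ValueError("reference panel is empty")
    identities = [
        (percent_identity(query_sequence, ref.sequence), ref) for ref in panel
    ]
    identities.sort(key=lambda pair: (-pair[0], pair[1].nau_name))
    best_identity, best_ref = identities[0]
    if best_identity < threshold:
        return HaplotypeCall(query_id, None, best_identity, CallStatus.NOVEL)
    rivals = {
        ref.nau_name
        for identity, ref in identities
        if best_identity - identity <= AMBIGUITY_MARGIN_PCT
    }
    if len(rivals) > 1:
        return HaplotypeCall(query_id, best_ref.nau_name, best_identity, CallStatus.AMBIGUOUS)
    return HaplotypeCall(query_id, best_ref.nau_name, best_identity, CallStatus.KNOWN)


def register_novel_call(call: HaplotypeCall, registry: Registry) -> HaplotypeCall:
    """Give a novel call its NAU-S name (naming delegated to the registry)."""
    if call.status is not CallStatus.NOVEL:
        raise ValueError(f"call for {call.query_id} is not novel")
    call.assigned_name = registry.register_novel(call.query_id)
    return call


def _round_half_up(value: float, places: int = 2) -> float:
    quantum = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class FrequencyTable:
    rows: list[tuple[str, int, float]]  # (nau_name, occurrences, frequency_pct)
    denominator: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["nau_name", "occurrences", "frequency_pct"]
        )

    def frequency(self, nau_name: str) -> float:
        for name, _, freq in self.rows:
            if name == nau_name:
                return freq
        raise KeyError(nau_name)


def tally_frequencies(calls: Sequence[HaplotypeCall]) -> FrequencyTable:
    """Occurrence counts and percentage frequencies of resolved calls.

    Frequencies are percentages of the call count, rounded half-up to two
    decimals; rows sorted by descending occurrences, then name.  Every
    call must be resolved (known, or novel with a registered name).
    """
    names = [call.resolved_name for call in calls]  # raises on unresolved
    denominator = len(names)
    counts: dict[str, int] = {}
    for name in names:
        counts[name] = counts.get(name, 0) + 1
    rows = [
        (name, count, _round_half_up(100.0 * count / denominator))
        for name, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return FrequencyTable(rows, denominator)


def heterozygote_resolve(
    genotype_id: str,
    class_I_call: HaplotypeCall,
    class_II_call: HaplotypeCall,
):
    """Combine the per-class calls of a Class I/II heterozygote.

    Each call names one of the genotype's two haplotypes; identical names
    on both slots are contradictory (one haplotype cannot be both the
    Class I and the Class II allele).
    """
    from .genetics import SGenotype  # local import: genetics is downstream

    name_I = class_I_call.resolved_name
    name_II = class_II_call.resolved_name
    if name_I == name_II:
        raise ValueError(
            f"{genotype_id}: both class slots resolve to {name_I}"
        )
    return SGenotype(
        genotype_id,
        frozenset({(name_I, "class_I"), (name_II, "class_II")}),
    )
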