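"""End-to-end S-haplotype typing: classify, profile, type, predict, report.

One call runs the whole desk pipeline on a genotype panel: virtual PCR
with both class-specific primer pairs partitions the genotypes into
Class I / Class II / Class I/II / none; Class I amplicons are digested
with HinfI into gel profiles; every amplicon is typed against the
reference panel by alignment identity (novel haplotypes get fresh NAU-S
numbers); heterozygotes are resolved to their two alleles; and, when
pollination records are supplied, cross predictions are scored against
the observed compatibility indices.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .amplify import (
    Amplicon,
    PrimerPair,
    SIClass,
    call_class,
    default_primer_pairs,
    virtual_pcr,
)
from .genetics import CrossOutcome, SGenotype, concordance, predict_cross
from .registry import Registry, UnifiedHaplotype
from .rflp import DEFAULT_MIN_DETECT, DEFAULT_RESOLUTION_PCT, HINFI, profile_table
from .simulate import PollinationRecord
from .typing import (
    DEFAULT_IDENTITY_THRESHOLD,
    CallStatus,
    FrequencyTable,
    HaplotypeCall,
    ReferenceHaplotype,
    assign_haplotype,
    heterozygote_resolve,
    register_novel_call,
    tally_frequencies,
)

__all__ = ["WorkflowError", "RunManifest", "WorkflowResult", "run_typing_workflow"]

logger = logging.getLogger("stype")


class WorkflowError(RuntimeError):
    def __init__(self, stage: str, record_id: str, message: str) -> None:
        super().__init__(f"[{stage}] {record_id}: {message}")
        self.stage = stage
        self.record_id = record_id


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    version: str
    threshold: float
    resolution_pct: float
    min_detect: int
    rng_seed: Optional[int]
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")


@dataclass
class WorkflowResult:
    class_calls: pd.DataFrame
    partition: pd.DataFrame
    class_I_frequencies: Optional[FrequencyTable]
    class_II_frequencies: Optional[FrequencyTable]
    heterozygotes: pd.DataFrame
    profile_count: int
    profile_assignments: dict[str, int]
    genotypes: dict[str, SGenotype]
    concordance_agreement: Optional[float]
    concordance_table: Optional[pd.DataFrame]
    manifest: RunManifest


def _round2(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _checksum(records: Sequence[tuple[str, str]]) -> str:
    h = hashlib.sha256()
    for name, seq in records:
        h.update(name.encode())
        h.update(seq.encode())
    return h.hexdigest()


def _registry_from_references(references: Sequence[ReferenceHaplotype]) -> Registry:
    registry = Registry()
    for ref in references:
        if ref.nau_name not in registry.haplotypes:
            registry.add(UnifiedHaplotype(ref.nau_name, frozenset(), ref.si_class))
    return registry


def run_typing_workflow(
    references: Sequence[ReferenceHaplotype],
    genotype_sequences: dict[str, list[tuple[str, str]]],
    pollination: Optional[Sequence[PollinationRecord]] = None,
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    resolution_pct: float = DEFAULT_RESOLUTION_PCT,
    min_detect: int = DEFAULT_MIN_DETECT,
    primer_pairs: Optional[dict[SIClass, PrimerPair]] = None,
    registry: Optional[Registry] = None,
    rng_seed: Optional[int] = None,
) -> WorkflowResult:
    """Run the full typing pipeline over a genotype panel.

    ``genotype_sequences`` maps genotype id to its sequence records (one
    per carried allele; record ids are free-form).  Returns the report
    bundle: class partition, per-class frequency tables, heterozygote
    table, gel-profile assignments, optional concordance report, and a
    run manifest.
    """
    if primer_pairs is None:
        primer_pairs = default_primer_pairs()
    if registry is None:
        registry = _registry_from_references(references)
    pair_I = primer_pairs[SIClass.CLASS_I]
    pair_II = primer_pairs[SIClass.CLASS_II]
    refs_I = [r for r in references if r.si_class == "class_I"]
    refs_II = [r for r in references if r.si_class == "class_II"]

    manifest = RunManifest(
        version=__version__,
        threshold=threshold,
        resolution_pct=resolution_pct,
        min_detect=min_detect,
        rng_seed=rng_seed,
    )
    for genotype_id, records in genotype_sequences.items():
        manifest.input_checksums[genotype_id] = _checksum(records)

    # ---- stage 1: virtual PCR classification -------------------------
    call_rows = []
    products: dict[str, dict[str, list[tuple[str, Amplicon]]]] = {}
    for genotype_id, records in genotype_sequences.items():
        prods_I: list[tuple[str, Amplicon]] = []
        prods_II: list[tuple[str, Amplicon]] = []
        try:
            for record_id, seq in records:
                for amp in virtual_pcr(record_id, seq, pair_I):
                    prods_I.append((seq, amp))
                for amp in virtual_pcr(record_id, seq, pair_II):
                    prods_II.append((seq, amp))
        except ValueError as exc:
            raise WorkflowError("amplify", genotype_id, str(exc)) from exc
        call = call_class(genotype_id, [a for _, a in prods_I], [a for _, a in prods_II])
        products[genotype_id] = {"class_I": prods_I, "class_II": prods_II}
        call_rows.append({"genotype_id": genotype_id, "call": call.call.value})
    class_calls = pd.DataFrame(call_rows, columns=["genotype_id", "call"])
    manifest.stage_counts["amplify"] = len(class_calls)
    logger.info("amplify: %d genotypes classified", len(class_calls))

    total = len(class_calls)
    buckets = ["class_I", "class_II", "class_I_II", "none"]
    counts = {b: int((class_calls["call"] == b).sum()) for b in buckets}
    partition = pd.DataFrame(
        {
            "si_class": buckets,
            "count": [counts[b] for b in buckets],
            "frequency_pct": [
                _round2(100.0 * counts[b] / total) if total else 0.0 for b in buckets
            ],
        }
    )

    # ---- stage 2: RFLP profiles of homozygous Class I genotypes ------
    rflp_panel = []
    for genotype_id, _ in class_calls[class_calls["call"] == "class_I"].itertuples(index=False):
        seq, amp = products[genotype_id]["class_I"][0]
        rflp_panel.append((genotype_id, seq[amp.start : amp.end]))
    try:
        profile_count, profile_assignments = profile_table(
            rflp_panel, HINFI, resolution_pct, min_detect
        )
    except ValueError as exc:
        raise WorkflowError("rflp", "panel", str(exc)) from exc
    manifest.stage_counts["rflp"] = len(rflp_panel)
    logger.info("rflp: %d profiles among %d Class I genotypes", profile_count, len(rflp_panel))

    # ---- stage 3: identity typing ------------------------------------
    def type_amplicon(genotype_id: str, si_class: str) -> HaplotypeCall:
        refs = refs_I if si_class == "class_I" else refs_II
        if not refs:
            raise WorkflowError("typing", genotype_id, f"no {si_class} references")
        seq, amp = products[genotype_id][si_class][0]
        call = assign_haplotype(genotype_id, seq[amp.start : amp.end], refs, threshold)
        if call.status is CallStatus.NOVEL:
            register_novel_call(call, registry)
        elif call.status is CallStatus.AMBIGUOUS:
            raise WorkflowError(
                "typing", genotype_id, f"ambiguous call near {call.best_hit}"
            )
        return call

    genotypes: dict[str, SGenotype] = {}
    calls_I: list[HaplotypeCall] = []
    calls_II: list[HaplotypeCall] = []
    het_rows = []
    for genotype_id, bucket in class_calls.itertuples(index=False):
        if bucket == "class_I":
            call = type_amplicon(genotype_id, "class_I")
            calls_I.append(call)
            genotypes[genotype_id] = SGenotype(
                genotype_id, frozenset({(call.resolved_name, "class_I")})
            )
        elif bucket == "class_II":
            call = type_amplicon(genotype_id, "class_II")
            calls_II.append(call)
            genotypes[genotype_id] = SGenotype(
                genotype_id, frozenset({(call.resolved_name, "class_II")})
            )
        elif bucket == "class_I_II":
            call_I = type_amplicon(genotype_id, "class_I")
            call_II = type_amplicon(genotype_id, "class_II")
            try:
                genotype = heterozygote_resolve(genotype_id, call_I, call_II)
            except ValueError as exc:
                raise WorkflowError("typing", genotype_id, str(exc)) from exc
            genotypes[genotype_id] = genotype
            het_rows.append(
                {
                    "genotype_id": genotype_id,
                    "class_I_haplotype": call_I.resolved_name,
                    "class_II_haplotype": call_II.resolved_name,
                }
            )
    heterozygotes = pd.DataFrame(
        het_rows, columns=["genotype_id", "class_I_haplotype", "class_II_haplotype"]
    )
    class_I_frequencies = tally_frequencies(calls_I) if calls_I else None
    class_II_frequencies = tally_frequencies(calls_II) if calls_II else None
    manifest.stage_counts["typing"] = len(calls_I) + len(calls_II) + 2 * len(het_rows)
    logger.info(
        "typing: %d Class I, %d Class II, %d heterozygous genotypes",
        len(calls_I), len(calls_II), len(het_rows),
    )

    # ---- stage 4: cross concordance ----------------------------------
    agreement = None
    concordance_df = None
    if pollination is not None:
        predictions = []
        outcomes = []
        for rec in pollination:
            for gid in (rec.female_id, rec.male_id):
                if gid not in genotypes:
                    raise WorkflowError("genetics", gid, "genotype was not typed")
            predictions.append(
                predict_cross(genotypes[rec.female_id], genotypes[rec.male_id], rec.stage)
            )
            outcomes.append(
                CrossOutcome(rec.female_id, rec.male_id, rec.n_flowers, rec.n_pods, rec.n_seeds)
            )
        agreement, concordance_df = concordance(predictions, outcomes)
        manifest.stage_counts["genetics"] = len(outcomes)
        logger.info("genetics: %d crosses scored", len(outcomes))

    return WorkflowResult(
        class_calls=class_calls,
        partition=partition,
        class_I_frequencies=class_I_frequencies,
        class_II_frequencies=class_II_frequencies,
        heterozygotes=heterozygotes,
        profile_count=profile_count,
        profile_assignments=profile_assignments,
        genotypes=genotypes,
        concordance_agreement=agreement,
        concordance_table=concordance_df,
        manifest=manifest,
    )
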