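"""Synthetic SRK kinase-domain panels, genotypes and pollination counts.

No public appendix carries the study's kinase-domain sequences, so the
pipeline is exercised on generated data that reproduces the features the
method depends on: ~1.0-1.4 kb templates carrying intact binding sites for
the class-specific degenerate primer pairs at offsets that yield the
published band sizes (~1200 bp Class I, ~1000 bp Class II), tunable
between-haplotype divergence, a distinct planted HinfI cut-site map per
Class I haplotype, homozygous and Class I/II heterozygous genotypes, and
noisy pollination counts whose compatibility index tracks the true
shared-haplotype state.

The mutation model is substitution-only, which keeps identity arithmetic
exact for truth checks.  HinfI maps are planted as explicit GANTC motifs
on a 50-nt lattice inside the amplicon, and every mutation or ancestral
position that would create an off-lattice GANTC is rejected, so the
planted map is the true map.  All generation is reproducible from the
configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import genetics
from ._iupac import IUPAC_SETS, revcomp
from .amplify import PrimerPair, Role, SIClass, default_primer_pairs, find_binding_sites
from .genetics import SGenotype, Stage
from .typing import ReferenceHaplotype

__all__ = [
    "SimulationConfig",
    "ReferenceTruth",
    "GenotypePanel",
    "PollinationRecord",
    "simulate_reference_panel",
    "simulate_genotype_panel",
    "simulate_pollination",
    "study_composition",
    "class_I_tally_composition",
    "write_fasta",
]

_BASES = "ACGT"

#: Forward primer is planted at this template offset.
_FORWARD_OFFSET = 100
#: Planted HinfI motifs sit on a 50-nt lattice inside the amplicon,
#: clear of both primers.
_SITE_LATTICE_STEP = 50
_SITE_LATTICE_MARGIN = 150


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the published panel: 19 Class I plus 4 Class II
    haplotype sequence types among 79 genotypes (48 homozygous Class I,
    13 homozygous Class II, 17 Class I/II heterozygotes), kinase-domain
    templates of 1.4 kb, within-haplotype divergence well below the
    between-haplotype divergence, and pollination counts whose
    compatibility index averages ~0.2 for incompatible and ~3.0 for
    compatible crosses with pod rates near 20% and 75%.
    """

    n_haplotypes: int = 23
    seq_length: int = 1400
    class_I_fraction: float = 19 / 23
    between_divergence: float = 0.08
    within_divergence: float = 0.002
    n_hinfI_sites: tuple[int, int] = (2, 6)
    panel_size: int = 79
    heterozygote_fraction: float = 17 / 79
    n_flowers_per_cross: int = 30
    seed_means: tuple[float, float] = (0.2, 3.0)   # (incompatible, compatible)
    pod_probs: tuple[float, float] = (0.2, 0.75)   # (incompatible, compatible)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes < 1 or self.panel_size < 1 or self.seq_length < 400:
            raise ValueError("counts must be >= 1 and seq_length >= 400")
        if not 0 <= self.class_I_fraction <= 1:
            raise ValueError("class_I_fraction outside [0, 1]")
        if not 0 <= self.heterozygote_fraction <= 1:
            raise ValueError("heterozygote_fraction outside [0, 1]")
        if not 0 <= self.within_divergence < self.between_divergence <= 1:
            raise ValueError("need 0 <= within_divergence < between_divergence <= 1")
        lo, hi = self.n_hinfI_sites
        if not 0 <= lo <= hi:
            raise ValueError("invalid n_hinfI_sites range")
        if self.n_flowers_per_cross < 1:
            raise ValueError("n_flowers_per_cross must be >= 1")


@dataclass(frozen=True)
class ReferenceTruth:
    """Planted ground truth for one reference haplotype."""

    nau_name: str
    si_class: str
    amplicon_start: int
    amplicon_end: int
    cut_positions: tuple[int, ...]  # absolute template coordinates


@dataclass
class GenotypePanel:
    """Simulated genotypes: per-allele sequences plus planted truth."""

    # genotype_id -> list of (allele nau_name, sequence)
    sequences: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    truth: dict[str, SGenotype] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.truth)


@dataclass(frozen=True)
class PollinationRecord:
    female_id: str
    male_id: str
    stage: Stage
    n_flowers: int
    n_pods: int
    n_seeds: int
    true_compatible: bool


def _realize(primer_iupac: str, rng: np.random.Generator) -> str:
    """Pick one concrete ACGT realization of a degenerate primer."""
    return "".join(
        sorted(IUPAC_SETS[c])[rng.integers(len(IUPAC_SETS[c]))] for c in primer_iupac
    )


def _creates_site(seq: list[str], pos: int) -> bool:
    """Does any GANTC window cover position pos?"""
    n = len(seq)
    for start in range(max(0, pos - 4), min(pos + 1, n - 4)):
        w = seq[start : start + 5]
        if w[0] == "G" and w[1] == "A" and w[3] == "T" and w[4] == "C":
            return True
    return False


def _scrub_sites(seq: list[str], protected: set[int], rng: np.random.Generator) -> None:
    """Destroy every GANTC whose window has an unprotected position."""
    n = len(seq)
    changed = True
    while changed:
        changed = False
        for start in range(n - 4):
            w = seq[start : start + 5]
            if not (w[0] == "G" and w[1] == "A" and w[3] == "T" and w[4] == "C"):
                continue
            free = [p for p in range(start, start + 5) if p not in protected]
            if not free:
                continue  # constant site inside a primer; harmless, identical in all
            pos = free[rng.integers(len(free))]
            choices = [b for b in _BASES if b != seq[pos]]
            seq[pos] = choices[rng.integers(3)]
            changed = True


def _mutate(
    seq: list[str],
    positions: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Substitute each position to a different base, never creating GANTC."""
    for pos in positions:
        original = seq[pos]
        for _ in range(12):
            new = _BASES[rng.integers(4)]
            if new == original:
                continue
            seq[pos] = new
            if not _creates_site(seq, pos):
                break
            seq[pos] = original
        # if every substitution creates a site, leave the position alone


def _amplicon_length(si_class: str) -> int:
    return 1200 if si_class == "class_I" else 1000


def _site_lattice(amp_start: int, amp_end: int) -> list[int]:
    return list(
        range(
            amp_start + _SITE_LATTICE_MARGIN,
            amp_end - _SITE_LATTICE_MARGIN,
            _SITE_LATTICE_STEP,
        )
    )


def simulate_reference_panel(
    config: SimulationConfig,
    names: Optional[Sequence[str]] = None,
    primer_pairs: Optional[dict[SIClass, PrimerPair]] = None,
) -> tuple[list[ReferenceHaplotype], dict[str, ReferenceTruth]]:
    """Generate divergent reference haplotypes with planted primer and site maps.

    Returns the references and a per-name truth record (amplicon span and
    HinfI cut positions).  Class I haplotypes receive pairwise-distinct
    cut-site maps whose gel profiles are also pairwise distinguishable at
    the default gel settings.
    """
    from .rflp import digest, gel_profile, profiles_equal  # avoid import cycle

    rng = np.random.default_rng(config.rng_seed)
    if primer_pairs is None:
        primer_pairs = default_primer_pairs()
    n_class_I = int(round(config.n_haplotypes * config.class_I_fraction))
    classes = ["class_I"] * n_class_I + ["class_II"] * (config.n_haplotypes - n_class_I)
    if names is None:
        names = [f"NAU-S{i}" for i in range(1, config.n_haplotypes + 1)]
    if len(names) != config.n_haplotypes:
        raise ValueError("names length != n_haplotypes")

    # One ancestor per class, with primers planted and GANTC scrubbed.
    ancestors: dict[str, list[str]] = {}
    protected_of: dict[str, set[int]] = {}
    span_of: dict[str, tuple[int, int]] = {}
    for si_class in ("class_I", "class_II"):
        pair = primer_pairs[SIClass(si_class)]
        amp_len = _amplicon_length(si_class)
        amp_start = _FORWARD_OFFSET
        amp_end = amp_start + amp_len
        if amp_end + 50 > config.seq_length:
            raise ValueError(
                f"seq_length {config.seq_length} too short for a {amp_len} nt amplicon"
            )
        seq = [
            _BASES[i] for i in rng.integers(4, size=config.seq_length)
        ]
        fwd = _realize(pair.forward.sequence, rng)
        rev_site = revcomp(_realize(pair.reverse.sequence, rng))
        seq[amp_start : amp_start + len(fwd)] = list(fwd)
        seq[amp_end - len(rev_site) : amp_end] = list(rev_site)
        protected = set(range(amp_start, amp_start + len(fwd)))
        protected |= set(range(amp_end - len(rev_site), amp_end))
        # lattice windows are overwritten or kept site-free; exclude from mutation
        lattice_windows = {
            p
            for site in _site_lattice(amp_start, amp_end)
            for p in range(site, site + 5)
        }
        _scrub_sites(seq, protected, rng)
        ancestors[si_class] = seq
        protected_of[si_class] = protected | lattice_windows
        span_of[si_class] = (amp_start, amp_end)

    lo_sites, hi_sites = config.n_hinfI_sites
    references: list[ReferenceHaplotype] = []
    truth: dict[str, ReferenceTruth] = {}
    used_maps: set[frozenset[int]] = set()
    class_I_profiles: list = []

    for name, si_class in zip(names, classes):
        ancestor = ancestors[si_class]
        protected = protected_of[si_class]
        amp_start, amp_end = span_of[si_class]
        lattice = _site_lattice(amp_start, amp_end)
        mutable = np.array(
            [p for p in range(config.seq_length) if p not in protected]
        )
        n_mut = int(round(config.between_divergence * config.seq_length))
        for _attempt in range(50):
            seq = list(ancestor)
            positions = rng.choice(mutable, size=min(n_mut, len(mutable)), replace=False)
            _mutate(seq, positions, rng)
            if si_class == "class_I" and hi_sites > 0:
                n_sites = int(rng.integers(lo_sites, hi_sites + 1))
                site_map = frozenset(
                    int(p) for p in rng.choice(lattice, size=n_sites, replace=False)
                )
                if site_map in used_maps:
                    continue
                for site in site_map:
                    motif = list("GANTC")
                    motif[2] = _BASES[rng.integers(4)]
                    seq[site : site + 5] = motif
                amplicon_seq = "".join(seq[amp_start:amp_end])
                profile = gel_profile(digest(amplicon_seq, source_id=name))
                if any(profiles_equal(profile, p) for p in class_I_profiles):
                    continue  # indistinguishable on the gel; redraw the map
                used_maps.add(site_map)
                class_I_profiles.append(profile)
                cuts = tuple(sorted(site + 1 for site in site_map))
            else:
                cuts = ()
            break
        else:
            raise ValueError(
                "could not draw a distinct, gel-resolvable HinfI site map; "
                "site lattice too small for the requested panel"
            )
        references.append(ReferenceHaplotype(name, si_class, "".join(seq)))
        truth[name] = ReferenceTruth(name, si_class, amp_start, amp_end, cuts)

    _check_cross_class_sites(references, primer_pairs)
    return references, truth


def _check_cross_class_sites(
    references: Sequence[ReferenceHaplotype],
    primer_pairs: dict[SIClass, PrimerPair],
) -> None:
    """Each reference must bind only its own class's primer pair."""
    for ref in references:
        for si_class, pair in primer_pairs.items():
            fwd = find_binding_sites(pair.forward, ref.sequence)
            rev = find_binding_sites(pair.reverse, ref.sequence)
            expected = si_class.value == ref.si_class
            has_product = bool(fwd) and bool(rev)
            if has_product != expected:
                raise RuntimeError(
                    f"{ref.nau_name}: unexpected {si_class.value} primer sites"
                )


def study_composition(
    references: Sequence[ReferenceHaplotype],
    n_hom_I: int = 48,
    n_hom_II: int = 13,
    n_het: int = 17,
    n_none: int = 1,
) -> list[tuple[str, ...]]:
    """A genotype composition with fixed class counts (default 48/13/17).

    Homozygotes cycle through the references of their class; heterozygotes
    pair a Class I with a Class II reference.  ``n_none`` genotypes carry
    no primer-binding sequence at all and amplify with neither pair: the
    published 79-material panel partitions into 48 + 13 + 17 classified
    genotypes (frequencies printed out of 79), leaving one material
    unaccounted for in every class bucket.
    """
    class_I = [r.nau_name for r in references if r.si_class == "class_I"]
    class_II = [r.nau_name for r in references if r.si_class == "class_II"]
    if n_hom_I and not class_I or n_hom_II and not class_II:
        raise ValueError("composition requests a class with no references")
    if n_het and (not class_I or not class_II):
        raise ValueError("heterozygotes need references of both classes")
    composition: list[tuple[str, ...]] = []
    composition += [("hom", class_I[i % len(class_I)]) for i in range(n_hom_I)]
    composition += [("hom", class_II[i % len(class_II)]) for i in range(n_hom_II)]
    composition += [
        ("het", class_I[i % len(class_I)], class_II[i % len(class_II)])
        for i in range(n_het)
    ]
    composition += [("none",)] * n_none
    return composition


def class_I_tally_composition(
    references: Sequence[ReferenceHaplotype],
    counts: Sequence[int] = (8, 7, 5, 4, 4, 3, 3, 2, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1),
) -> list[tuple[str, ...]]:
    """Homozygous Class I genotypes with a planted occurrence multiset.

    The default multiset is the published Class I tally: 19 haplotypes
    carried by 48 genotypes with occurrence counts 8,7,5,4,4,3,3,2,2 and
    ten singletons.
    """
    class_I = [r.nau_name for r in references if r.si_class == "class_I"]
    if len(class_I) < len(counts):
        raise ValueError(
            f"need {len(counts)} Class I references, have {len(class_I)}"
        )
    composition: list[tuple[str, ...]] = []
    for name, count in zip(class_I, counts):
        composition += [("hom", name)] * count
    return composition


def simulate_genotype_panel(
    references: Sequence[ReferenceHaplotype],
    config: SimulationConfig,
    composition: Optional[Sequence[tuple[str, ...]]] = None,
    id_prefix: str = "Rs",
) -> GenotypePanel:
    """Draw a diploid genotype panel carrying re-mutated reference alleles.

    Without an explicit composition, each genotype is heterozygous
    (one Class I plus one Class II allele) with probability
    ``heterozygote_fraction``, otherwise homozygous for a random
    reference.  Each carried allele copy is re-mutated at the
    within-haplotype divergence.  One sequence per carried allele is
    emitted, so heterozygotes contribute two records.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    by_name = {r.nau_name: r for r in references}
    class_I = [r.nau_name for r in references if r.si_class == "class_I"]
    class_II = [r.nau_name for r in references if r.si_class == "class_II"]

    if composition is None:
        composition = []
        for _ in range(config.panel_size):
            if rng.random() < config.heterozygote_fraction:
                if not class_I or not class_II:
                    raise ValueError("heterozygote requested but a class has no references")
                composition.append(
                    ("het",
                     class_I[rng.integers(len(class_I))],
                     class_II[rng.integers(len(class_II))])
                )
            else:
                all_names = [r.nau_name for r in references]
                composition.append(("hom", all_names[rng.integers(len(all_names))]))

    panel = GenotypePanel()
    n_within = int(round(config.within_divergence * config.seq_length))
    for i, entry in enumerate(composition, start=1):
        genotype_id = f"{id_prefix}{i}"
        kind, *allele_names = entry
        if kind == "hom":
            carried = [allele_names[0]]
        elif kind == "het":
            carried = list(allele_names)
        elif kind == "none":
            # off-target material: random sequence, no primer sites planted
            seq = "".join(_BASES[b] for b in rng.integers(4, size=config.seq_length))
            panel.sequences[genotype_id] = [("off_target", seq)]
            continue
        else:
            raise ValueError(f"unknown composition entry kind {kind!r}")
        records = []
        for name in carried:
            ref = by_name[name]
            seq = list(ref.sequence)
            if n_within:
                # keep planted primer sites and HinfI map intact, as in the refs
                protected = _allele_protected(ref)
                mutable = np.array(
                    [p for p in range(len(seq)) if p not in protected]
                )
                positions = rng.choice(mutable, size=n_within, replace=False)
                _mutate(seq, positions, rng)
            records.append((name, "".join(seq)))
        haplotypes = frozenset((name, by_name[name].si_class) for name in carried)
        panel.sequences[genotype_id] = records
        panel.truth[genotype_id] = SGenotype(genotype_id, haplotypes)
    return panel


def _allele_protected(ref: ReferenceHaplotype) -> set[int]:
    amp_len = _amplicon_length(ref.si_class)
    amp_start, amp_end = _FORWARD_OFFSET, _FORWARD_OFFSET + amp_len
    protected = set(range(amp_start, amp_start + 30))
    protected |= set(range(amp_end - 30, amp_end))
    protected |= {
        p
        for site in _site_lattice(amp_start, amp_end)
        for p in range(site, site + 5)
    }
    return protected


def simulate_pollination(
    truth: dict[str, SGenotype],
    crosses: Sequence[tuple[str, str, Stage | str]],
    config: SimulationConfig,
    noise: bool = True,
) -> list[PollinationRecord]:
    """Draw pollination counts whose statistics track true compatibility.

    Seeds per cross are Poisson with mean n_flowers x (0.2 incompatible /
    3.0 compatible by default); pods are per-flower Bernoulli at ~20% vs
    ~75%.  With ``noise=False`` the expectations are used directly
    (rounded), which pins the compatibility index at its mean.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    incompatible_mean, compatible_mean = config.seed_means
    pod_p_incompatible, pod_p_compatible = config.pod_probs
    records = []
    for female_id, male_id, stage in crosses:
        if female_id not in truth or male_id not in truth:
            missing = female_id if female_id not in truth else male_id
            raise KeyError(f"unknown genotype id {missing!r}")
        prediction = genetics.predict_cross(
            truth[female_id], truth[male_id], Stage(stage)
        )
        compatible = prediction.predicted == "compatible"
        seed_mean = compatible_mean if compatible else incompatible_mean
        pod_p = pod_p_compatible if compatible else pod_p_incompatible
        n = config.n_flowers_per_cross
        if noise:
            n_seeds = int(rng.poisson(n * seed_mean))
            n_pods = int(rng.binomial(n, pod_p))
        else:
            n_seeds = int(round(n * seed_mean))
            n_pods = int(round(n * pod_p))
        records.append(
            PollinationRecord(
                female_id, male_id, Stage(stage), n, n_pods, n_seeds, compatible
            )
        )
    return records


def write_fasta(
    path,
    records: Sequence[tuple[str, str]],
    line_width: int = 70,
) -> None:
    """Write (id, sequence) records as FASTA."""
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
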