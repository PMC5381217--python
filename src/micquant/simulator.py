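"""Synthetic amplicon experiments with the statistical structure of
compartmentalized (micelle) versus bulk (traditional) PCR.

The generator produces per-replicate OTU read-count profiles, together with
full ground truth, for an equimolar dilution series with an internal
calibrator spike, reagent-lot and environmental contamination, chimera
formation, multinomial sequencing and rarefaction. It emulates the
*statistical* consequences of the two amplification chemistries, not the
chemistry itself:

* **Micelle PCR** — each template molecule amplifies clonally in its own
  compartment. Per-molecule yield varies with compartment volume, modelled
  as i.i.d. log-normal; per-OTU amplicon mass is the sum over its molecules,
  with no cross-OTU interaction. Noise therefore averages out with template
  number, and chimera formation is negligible.
* **Bulk PCR** — all templates compete in one volume. Each OTU draws a
  single per-replicate amplification efficiency, compounded over the cycle
  count, so small efficiency differences explode into large between-replicate
  copy-number dispersion; a few percent of reads are chimeric.

Noise is modelled at the replicate level (final read counts), not as a
cycle-by-cycle branching process: the downstream analysis consumes only
final counts, and replicate-level multiplicative noise reproduces the
qualitative precision contrast between the two chemistries at trivial cost.

All randomness flows from one master seed through a documented hierarchy
(experiment -> sample -> stage) built on ``numpy.random.SeedSequence.spawn``,
so every stage is independently reproducible and the whole experiment is
bit-identical across runs with the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .calibration import ReadProfile, recommend_spike, rarefy
from .io_tables import CountTable, SampleMetadata

import pandas as pd

__all__ = [
    "SimulationConfig",
    "ReplicateTruth",
    "SimulatedGroup",
    "SimulatedExperiment",
    "EmptyLibraryError",
    "draw_templates",
    "amplify_micelle",
    "amplify_bulk",
    "sequence_reads",
    "simulate_replicate",
    "simulate_experiment",
    "DEFAULT_TAXA",
]

#: The four equimolar community members of the validation series.
DEFAULT_TAXA = ("Clostridium", "Staphylococcus", "Haemophilus", "Moraxella")

#: A reagent "lot": taxa whose DNA ships with the extraction/PCR chemicals,
#: hence reproducibly present in every library made with that lot.
DEFAULT_REAGENT_CONTAMINANTS = (
    ("Ralstonia_reagent", 30.0),
    ("Bradyrhizobium_reagent", 15.0),
    ("Pseudomonas_reagent", 8.0),
)

#: Taxa that can drift in sporadically from the processing environment.
DEFAULT_ENV_POOL = (
    "Cutibacterium_env",
    "Corynebacterium_env",
    "Micrococcus_env",
    "Streptococcus_env",
    "Acinetobacter_env",
    "Sphingomonas_env",
    "Methylobacterium_env",
    "Escherichia_env",
)

PROVENANCE_COMMUNITY = "community"
PROVENANCE_IC = "ic"
PROVENANCE_REAGENT = "reagent"
PROVENANCE_ENVIRONMENTAL = "environmental"
PROVENANCE_CHIMERA = "chimera"


class EmptyLibraryError(RuntimeError):
    """Total amplification failure: no amplicon mass to sequence."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated amplification/sequencing run.

    Defaults reproduce the validation-study conditions: ~30 PCR cycles, a
    sequencing depth of a few thousand reads rarefied to 1,000, chimera
    rates of ~0.01% (micelle) versus ~4.5% (bulk), and a mean of two
    sporadic environmental contaminants per replicate.
    """

    taxa: tuple[tuple[str, float], ...] = ()  # (otu_id, 16S copies per reaction)
    ic_otu_id: str = "Synechococcus_IC"
    ic_spike_copies: float = 50.0
    method: str = "micelle"  # "micelle" | "traditional"
    cycles: int = 30
    micelle_yield_sigma: float = 0.3  # log-scale SD of per-template clonal yield
    bulk_efficiency_range: tuple[float, float] = (0.85, 0.95)
    chimera_fraction: float | None = None  # None -> per-method default
    chimera_detection_sensitivity: float = 0.95
    reagent_contaminants: tuple[tuple[str, float], ...] = DEFAULT_REAGENT_CONTAMINANTS
    env_contaminant_pool: tuple[str, ...] = DEFAULT_ENV_POOL
    env_rate: float = 2.0  # mean sporadic contaminant taxa per replicate
    env_copies_logmean: float = math.log(10.0)
    env_copies_logsd: float = 1.0
    depth_mean: int = 5000
    rarefaction_depth: int = 1000
    host_dna_excess: bool = False  # bulk-PCR inhibition by host DNA
    host_failure_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.method not in ("micelle", "traditional"):
            raise ValueError(f"method must be 'micelle' or 'traditional', got {self.method!r}")
        lo, hi = self.bulk_efficiency_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("bulk_efficiency_range must lie within (0, 1]")
        if self.chimera_fraction is not None and not 0 <= self.chimera_fraction < 1:
            raise ValueError("chimera_fraction must be in [0, 1)")
        if not 0 <= self.chimera_detection_sensitivity <= 1:
            raise ValueError("chimera_detection_sensitivity must be in [0, 1]")
        if self.env_rate < 0 or self.micelle_yield_sigma < 0:
            raise ValueError("rates and sigmas must be non-negative")
        ids = [t for t, _ in self.taxa]
        if len(set(ids)) != len(ids) or self.ic_otu_id in ids:
            raise ValueError("taxa ids must be unique and disjoint from the calibrator")

    @property
    def effective_chimera_fraction(self) -> float:
        if self.chimera_fraction is not None:
            return self.chimera_fraction
        return 0.0001 if self.method == "micelle" else 0.045


@dataclass(frozen=True)
class ReplicateTruth:
    """Ground truth for one simulated replicate."""

    sample_id: str
    templates: dict[str, int]  # realized template molecules per OTU
    provenance: dict[str, str]  # OTU -> community|ic|reagent|environmental|chimera
    pre_qc_chimera_reads: int


@dataclass(frozen=True)
class SimulatedGroup:
    group_id: str
    role: str  # specimen | nec
    level: float | None  # input copies per community taxon; None for NEC
    profiles: tuple[ReadProfile, ...]
    truths: tuple[ReplicateTruth, ...]


@dataclass(frozen=True)
class SimulatedExperiment:
    groups: tuple[SimulatedGroup, ...]
    config: SimulationConfig
    master_seed: int

    def metadata(self) -> list[SampleMetadata]:
        out = []
        for g in self.groups:
            for i, p in enumerate(g.profiles, start=1):
                out.append(
                    SampleMetadata(
                        sample_id=p.sample_id,
                        replicate_index=i,
                        role=g.role,
                        ic_otu_id=p.ic_otu_id,
                        ic_spike_copies=p.ic_spike_copies,
                        group_id=g.group_id,
                        expected_copies_per_taxon=g.level,
                    )
                )
        return out

    def count_table(self) -> CountTable:
        profiles = [p for g in self.groups for p in g.profiles]
        otus = sorted({o for p in profiles for o in p.otu_reads})
        data = {
            p.sample_id: [p.otu_reads.get(o, 0) for o in otus] for p in profiles
        }
        df = pd.DataFrame(data, index=pd.Index(otus, name="otu_id"), dtype="int64")
        return CountTable(df)


def _rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_templates(
    config: SimulationConfig, seed: int | np.random.Generator
) -> tuple[dict[str, int], dict[str, str]]:
    """Realize template molecule counts for one reaction.

    Community taxa, the calibrator spike and reagent contaminants are
    Poisson-distributed around their nominal copy numbers (pipetting a
    dilute DNA solution is molecule counting); environmental contamination
    hits Poisson(env_rate) distinct pool taxa with log-normal nominal
    copies, Poisson-realized. Returns (templates, provenance).
    """
    rng = _rng(seed)
    templates: dict[str, int] = {}
    provenance: dict[str, str] = {}

    for otu, copies in config.taxa:
        templates[otu] = int(rng.poisson(copies))
        provenance[otu] = PROVENANCE_COMMUNITY
    templates[config.ic_otu_id] = int(rng.poisson(config.ic_spike_copies))
    provenance[config.ic_otu_id] = PROVENANCE_IC
    for otu, copies in config.reagent_contaminants:
        templates[otu] = templates.get(otu, 0) + int(rng.poisson(copies))
        provenance[otu] = PROVENANCE_REAGENT

    pool = list(config.env_contaminant_pool)
    if pool and config.env_rate > 0:
        k = min(int(rng.poisson(config.env_rate)), len(pool))
        hit = rng.choice(len(pool), size=k, replace=False)
        for idx in hit:
            otu = pool[int(idx)]
            nominal = float(rng.lognormal(config.env_copies_logmean, config.env_copies_logsd))
            n = int(rng.poisson(nominal))
            if n > 0:
                templates[otu] = templates.get(otu, 0) + n
                provenance[otu] = PROVENANCE_ENVIRONMENTAL
    return templates, provenance


def amplify_micelle(
    templates: dict[str, int], config: SimulationConfig, seed: int | np.random.Generator
) -> dict[str, float]:
    """Clonal compartmentalized amplification.

    Each template molecule independently contributes a log-normal(0, sigma)
    yield (compartment-volume stochasticity); per-OTU mass is the sum over
    its molecules. No cross-OTU interaction of any kind.
    """
    rng = _rng(seed)
    masses: dict[str, float] = {}
    for otu, n in templates.items():
        if n <= 0:
            masses[otu] = 0.0
        elif config.micelle_yield_sigma == 0:
            masses[otu] = float(n)
        else:
            masses[otu] = float(rng.lognormal(0.0, config.micelle_yield_sigma, size=n).sum())
    return masses


def amplify_bulk(
    templates: dict[str, int], config: SimulationConfig, seed: int | np.random.Generator
) -> dict[str, float]:
    """Single-volume competitive amplification.

    Each OTU draws one per-replicate efficiency E ~ U(bulk_efficiency_range)
    and its mass is templates * (1+E)^cycles. Compounding over the cycles
    turns small efficiency differences into large between-replicate
    copy-number dispersion — the signature imprecision of bulk PCR.
    """
    rng = _rng(seed)
    lo, hi = config.bulk_efficiency_range
    masses: dict[str, float] = {}
    for otu, n in templates.items():
        eff = float(rng.uniform(lo, hi))
        masses[otu] = float(n) * (1.0 + eff) ** config.cycles if n > 0 else 0.0
    return masses


def sequence_reads(
    masses: dict[str, float],
    config: SimulationConfig,
    seed: int | np.random.Generator,
    sample_id: str = "sim",
    provenance: dict[str, str] | None = None,
    templates: dict[str, int] | None = None,
) -> tuple[ReadProfile, ReplicateTruth]:
    """Sample sequencing reads from amplicon masses and apply chimera QC.

    Reads are multinomial over mass proportions at ``depth_mean``. A
    binomial share of reads (``chimera_fraction``) is relabeled chimeric;
    of those, ``chimera_detection_sensitivity`` are recognized and removed
    (emulating reference-based chimera screening), while survivors are
    assigned to composite OTU ids of two mass-weighted parents and inflate
    the distinct-OTU count. Finally the library is rarefied to
    ``rarefaction_depth``.
    """
    rng = _rng(seed)
    otus = sorted(masses)
    mass_vec = np.asarray([masses[o] for o in otus], dtype=float)
    total = mass_vec.sum()
    if total <= 0:
        raise EmptyLibraryError(f"{sample_id}: no amplicon mass to sequence")
    reads_vec = rng.multinomial(config.depth_mean, mass_vec / total)
    reads = {o: int(r) for o, r in zip(otus, reads_vec)}

    provenance = dict(provenance or {})
    frac = config.effective_chimera_fraction
    n_chimeric = int(rng.binomial(config.depth_mean, frac)) if frac > 0 else 0
    if n_chimeric > 0:
        # chimeric reads come out of their parent OTUs' read mass
        pulled = rng.multivariate_hypergeometric(reads_vec, n_chimeric)
        for o, k in zip(otus, pulled):
            reads[o] -= int(k)
        detected = int(rng.binomial(n_chimeric, config.chimera_detection_sensitivity))
        survivors = n_chimeric - detected
        if survivors > 0:
            parent_p = mass_vec / total
            for _ in range(survivors):
                a, b = rng.choice(len(otus), size=2, replace=True, p=parent_p)
                chim_id = f"chimera:{otus[int(a)]}+{otus[int(b)]}"
                reads[chim_id] = reads.get(chim_id, 0) + 1
                provenance[chim_id] = PROVENANCE_CHIMERA

    post_qc_total = sum(reads.values())
    rarefied = rarefy(reads, config.rarefaction_depth, rng) if post_qc_total >= config.rarefaction_depth else None
    if rarefied is None:
        from .calibration import InsufficientDepthError

        raise InsufficientDepthError(
            f"{sample_id}: {post_qc_total} QC-passed reads < rarefaction depth "
            f"{config.rarefaction_depth}"
        )
    rarefied.setdefault(config.ic_otu_id, 0)
    profile = ReadProfile(
        sample_id=sample_id,
        otu_reads=rarefied,
        ic_otu_id=config.ic_otu_id,
        ic_spike_copies=config.ic_spike_copies,
    )
    truth = ReplicateTruth(
        sample_id=sample_id,
        templates=dict(templates or {}),
        provenance=provenance,
        pre_qc_chimera_reads=n_chimeric,
    )
    return profile, truth


def simulate_replicate(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
    sample_id: str = "sim",
) -> tuple[ReadProfile, ReplicateTruth]:
    """One full replicate: templates -> amplification -> sequencing.

    With ``host_dna_excess`` set, a bulk-PCR library fails outright with
    probability ``host_failure_prob`` (host DNA inhibits/outcompetes the
    reaction); compartmentalized reactions are immune, since inhibitors are
    confined to their own compartments.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_templates, s_amplify, s_sequence, s_host = ss.spawn(4)
    templates, provenance = draw_templates(config, np.random.default_rng(s_templates))
    if config.host_dna_excess and config.method == "traditional":
        if np.random.default_rng(s_host).random() < config.host_failure_prob:
            raise EmptyLibraryError(f"{sample_id}: bulk PCR inhibited by host DNA excess")
    if config.method == "micelle":
        masses = amplify_micelle(templates, config, np.random.default_rng(s_amplify))
    else:
        masses = amplify_bulk(templates, config, np.random.default_rng(s_amplify))
    return sequence_reads(
        masses,
        config,
        np.random.default_rng(s_sequence),
        sample_id=sample_id,
        provenance=provenance,
        templates=templates,
    )


def simulate_experiment(
    series_levels: Sequence[float],
    config: SimulationConfig,
    seed: int,
    taxa_ids: Sequence[str] = DEFAULT_TAXA,
) -> SimulatedExperiment:
    """Simulate an equimolar dilution series plus a NEC triplicate.

    For each level (input 16S copies per taxon, descending), three replicates
    of the equimolar community are generated; the calibrator spike follows
    the 10%-of-total-with-50-copy-floor rule. The NEC triplicate carries no
    community DNA — contamination and calibrator only.
    """
    levels = [float(x) for x in series_levels]
    if not levels or any(x <= 0 for x in levels):
        raise ValueError("series levels must be positive")
    if levels != sorted(levels, reverse=True):
        raise ValueError("series levels must be in descending order")

    master = np.random.SeedSequence(int(seed))
    groups: list[SimulatedGroup] = []
    sample_seeds = master.spawn((len(levels) + 1) * 3)
    seed_iter = iter(sample_seeds)

    for level in levels:
        level_tag = f"{level:g}"
        taxa = tuple((t, level) for t in taxa_ids)
        spike = recommend_spike(level * len(taxa_ids))
        cfg = replace(config, taxa=taxa, ic_spike_copies=spike)
        profiles, truths = [], []
        for rep in (1, 2, 3):
            sid = f"SMC{level_tag}_{config.method}_r{rep}"
            p, t = simulate_replicate(cfg, next(seed_iter), sample_id=sid)
            profiles.append(p)
            truths.append(t)
        groups.append(
            SimulatedGroup(
                group_id=f"SMC{level_tag}_{config.method}",
                role="specimen",
                level=level,
                profiles=tuple(profiles),
                truths=tuple(truths),
            )
        )

    nec_cfg = replace(config, taxa=(), ic_spike_copies=recommend_spike(0.0))
    profiles, truths = [], []
    for rep in (1, 2, 3):
        sid = f"NEC_{config.method}_r{rep}"
        p, t = simulate_replicate(nec_cfg, next(seed_iter), sample_id=sid)
        profiles.append(p)
        truths.append(t)
    groups.append(
        SimulatedGroup(
            group_id=f"NEC_{config.method}",
            role="nec",
            level=None,
            profiles=tuple(profiles),
            truths=tuple(truths),
        )
    )
    return SimulatedExperiment(tuple(groups), config, int(seed))
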