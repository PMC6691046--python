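"""Synthetic multi-panel cytometry cohorts with ground-truth cell identities.

The generator emulates the structure a multi-tube mass-cytometry experiment
produces: each individual's leukocytes are a mixture of populations (T cells,
B cells, PMNs, NK cells, monocytes, dendritic cells, basophils, ...); the same
cells are "stained" by several antibody panels that share a backbone marker
set; each panel sees only its own markers, adds its own measurement noise on
the backbone, and stores events in its own (shuffled) order.  Ground truth --
which population each cell came from, and which rows across panels are the
same physical cell -- travels alongside so that every downstream stage
(matching, clustering, phenotyping, group testing) can be scored.

Populations are diagonal Gaussians directly in arcsinh intensity space; the
model makes no claim about raw ion-count physics, it exists to give the
pipeline mixtures with known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError
from .profiles import CytometricProfile, PanelDefinition, PanelSet, subset_markers

__all__ = [
    "PopulationSpec",
    "CohortSpec",
    "GroundTruth",
    "generate_individual",
    "split_panels",
    "generate_cohort",
    "make_hiv_cohort_preset",
    "BACKBONE_MARKERS",
    "HIV_SHIFTED_MARKERS",
]

#: The 14 markers shared by the three preset panels; the merge backbone.
BACKBONE_MARKERS = (
    "CD1c", "CD3", "CD11c", "CD14", "CD16", "CD19", "CD32",
    "CD64", "CD66", "CD86", "CD123", "CD141", "GranzymeB", "HLADR",
)

_PANEL_A_SPECIFIC = (
    "CD8a", "IL-6", "GranzymeA", "IL-1b", "IL-8", "CD23", "MIP-1b",
    "IP-10", "TNFa", "IL-1a", "IL-12", "CXCR4", "TLR2", "CCR5",
    "CD28", "IFNa", "CD45RA", "IFNg", "CD4", "IL-1RA", "MCP-1",
)
_PANEL_B_SPECIFIC = (
    "CCR7", "NF-ATC", "CD335", "IL-4", "CD107a", "CD154", "CD54",
    "IL-2", "CD69", "Ki67", "CD25", "CD11a", "CD11b", "CD38",
    "IgG2b", "IL-10", "MyD88", "Perforin",
)
_PANEL_C_SPECIFIC = (
    "CD209", "CD62L", "CD45", "CD137", "CXCR3", "CD56", "ITGb7",
    "Bcl-6", "CD83", "CD279", "CD127", "IL-10R", "CD27", "IgG2c",
    "CCL5", "IgG1K", "IL-2RA", "IgG2a", "NFkB",
)

#: Markers upregulated on monocytes and PMNs under the HIV condition in the preset.
HIV_SHIFTED_MARKERS = (
    "CD11a", "CD11b", "CD32", "CD38", "CD64", "CD83", "CD86", "TLR2",
)


@dataclass(frozen=True)
class PopulationSpec:
    """One leukocyte population: diagonal-Gaussian marker model + abundances.

    ``mean``/``sd`` map every marker of the cohort's universe to arcsinh-unit
    location and spread.  ``abundance`` gives the relative weight of the
    population per condition.  ``condition_shifts`` optionally adds a
    per-condition offset to selected marker means -- the hook used to encode
    disease-dependent marker upregulation.
    """

    name: str
    mean: dict
    sd: dict
    abundance: dict
    condition_shifts: dict = field(default_factory=dict)

    def mean_vector(self, markers, condition: str) -> np.ndarray:
        shift = self.condition_shifts.get(condition, {})
        return np.asarray([self.mean[m] + shift.get(m, 0.0) for m in markers])

    def sd_vector(self, markers) -> np.ndarray:
        return np.asarray([self.sd[m] for m in markers])


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic multi-panel cohort."""

    populations: tuple[PopulationSpec, ...]
    marker_universe: tuple[str, ...]
    panels: tuple[PanelDefinition, ...]
    individuals: tuple[tuple[str, str], ...]  # (individual id, condition)
    n_events: int = 5000
    backbone_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "marker_universe", tuple(self.marker_universe))
        object.__setattr__(self, "panels", tuple(self.panels))
        object.__setattr__(self, "individuals", tuple((i, c) for i, c in self.individuals))
        union = set().union(*(set(p.markers) for p in self.panels)) if self.panels else set()
        if union != set(self.marker_universe):
            raise SpecError("union of panel markers must equal the marker universe")
        backbones = {frozenset(p.backbone) for p in self.panels}
        if len(backbones) > 1:
            raise SpecError("all panels must share an identical backbone set")
        for pop in self.populations:
            for m in self.marker_universe:
                if m not in pop.mean or m not in pop.sd:
                    raise SpecError(f"population {pop.name}: no model for marker {m}")
                if not pop.sd[m] > 0:
                    raise SpecError(f"population {pop.name}: sd must be > 0 for {m}")
        if self.n_events < 1:
            raise SpecError("n_events must be positive")
        if self.backbone_noise_sd < 0:
            raise SpecError("backbone_noise_sd must be nonnegative")
        for condition in {c for _, c in self.individuals}:
            weights = [pop.abundance.get(condition, 0.0) for pop in self.populations]
            if any(w < 0 for w in weights):
                raise SpecError(f"negative abundance weight in condition {condition}")
            if sum(weights) <= 0:
                raise SpecError(f"condition {condition} has all-zero population weights")

    @property
    def conditions(self) -> dict:
        return dict(self.individuals)

    def condition_of(self, individual_id: str) -> str:
        try:
            return self.conditions[individual_id]
        except KeyError:
            raise SpecError(f"unknown individual: {individual_id}") from None


@dataclass
class GroundTruth:
    """True cell identities for one synthetic individual.

    ``populations[i]`` is the population name of event id ``i`` in the
    full-universe profile; ``panel_orders[panel_id][r]`` is the event id
    occupying row ``r`` of that panel's (shuffled) profile.
    """

    individual_id: str
    populations: np.ndarray
    panel_orders: dict = field(default_factory=dict)

    def population_mask(self, name: str) -> np.ndarray:
        return self.populations == name


def _individual_rng(spec: CohortSpec, individual_id: str, seed: int | None) -> np.random.Generator:
    base = spec.seed if seed is None else seed
    # stable per-individual stream: hash the id into the seed sequence
    tag = [ord(c) for c in individual_id]
    return np.random.default_rng(np.random.SeedSequence([int(base), *tag]))


def generate_individual(
    spec: CohortSpec, individual_id: str, seed: int | None = None
) -> tuple[CytometricProfile, GroundTruth]:
    """Draw one individual's full-universe profile plus its ground truth.

    Population labels are sampled with the individual's condition-normalised
    abundance weights; each marker is then drawn independently
    ``Normal(mean, sd)`` for the assigned population.  The returned profile is
    in arcsinh units (transformed flag set) with event ids ``0..n-1``.
    """
    condition = spec.condition_of(individual_id)
    rng = _individual_rng(spec, individual_id, seed)
    weights = np.asarray([pop.abundance.get(condition, 0.0) for pop in spec.populations])
    weights = weights / weights.sum()
    labels = rng.choice(len(spec.populations), size=spec.n_events, p=weights)

    markers = spec.marker_universe
    means = np.stack([pop.mean_vector(markers, condition) for pop in spec.populations])
    sds = np.stack([pop.sd_vector(markers) for pop in spec.populations])
    events = means[labels] + rng.standard_normal((spec.n_events, len(markers))) * sds[labels]

    profile = CytometricProfile(
        events=events,
        markers=list(markers),
        sample_id=individual_id,
        panel_id="full",
        transformed=True,
        event_ids=np.arange(spec.n_events),
    )
    names = np.asarray([pop.name for pop in spec.populations])
    truth = GroundTruth(individual_id=individual_id, populations=names[labels])
    return profile, truth


def split_panels(
    full: CytometricProfile,
    truth: GroundTruth,
    panels,
    backbone_noise_sd: float = 0.0,
    seed: int = 0,
) -> PanelSet:
    """Split a full-universe profile into per-panel profiles.

    Each panel keeps only its own markers; its backbone columns receive
    independent ``Normal(0, backbone_noise_sd)`` perturbations (panel-specific
    staining/measurement noise); its rows are shuffled independently.  Event
    ids are carried along for truth scoring only -- the merge stage never
    looks at them.
    """
    panels = list(panels)
    universe = set(full.markers)
    for panel in panels:
        missing = set(panel.markers) - universe
        if missing:
            raise SpecError(f"panel {panel.panel_id}: markers not in universe: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    profiles: dict[str, CytometricProfile] = {}
    backbone = panels[0].backbone
    for panel in panels:
        prof = subset_markers(full, list(panel.markers))
        bb_idx = prof.marker_index(panel.backbone)
        noisy = prof.events.copy()
        if backbone_noise_sd > 0:
            noisy[:, bb_idx] += rng.standard_normal((prof.n_events, len(bb_idx))) * backbone_noise_sd
        order = rng.permutation(prof.n_events)
        event_ids = full.event_ids[order] if full.event_ids is not None else order
        profiles[panel.panel_id] = CytometricProfile(
            events=noisy[order],
            markers=list(panel.markers),
            sample_id=full.sample_id,
            panel_id=panel.panel_id,
            transformed=full.transformed,
            event_ids=np.asarray(event_ids),
        )
        truth.panel_orders[panel.panel_id] = np.asarray(event_ids)
    return PanelSet(sample_id=full.sample_id, profiles=profiles, backbone=backbone)


def generate_cohort(spec: CohortSpec) -> dict:
    """Generate every individual of the cohort.

    Returns ``{individual_id: (full_profile, PanelSet, GroundTruth)}``.
    Identical spec (including seed) gives bit-identical output.
    """
    out = {}
    for idx, (individual_id, _) in enumerate(spec.individuals):
        full, truth = generate_individual(spec, individual_id)
        panelset = split_panels(
            full, truth, spec.panels,
            backbone_noise_sd=spec.backbone_noise_sd,
            seed=spec.seed * 100_003 + idx,
        )
        out[individual_id] = (full, panelset, truth)
    return out


def _preset_panels() -> tuple[PanelDefinition, ...]:
    return (
        PanelDefinition("#A", BACKBONE_MARKERS + _PANEL_A_SPECIFIC, BACKBONE_MARKERS),
        PanelDefinition("#B", BACKBONE_MARKERS + _PANEL_B_SPECIFIC, BACKBONE_MARKERS),
        PanelDefinition("#C", BACKBONE_MARKERS + _PANEL_C_SPECIFIC, BACKBONE_MARKERS),
    )


def make_hiv_cohort_preset(seed: int = 0, n_events: int = 5000) -> CohortSpec:
    """Ready-made two-condition cohort: 3 healthy (HEA) + 3 HIV individuals.

    Eight leukocyte populations measured by three panels of 35/32/33 markers
    sharing the 14-marker backbone.  Under the HIV condition, monocytes and
    PMNs upregulate CD11a, CD11b, CD32, CD38, CD64, CD83, CD86 and TLR2 by
    2.2 arcsinh units -- a deliberately clean encoding of the activation
    phenotype this kind of cohort shows, so enrichment and directionality are
    recoverable by construction.
    """
    panels = _preset_panels()
    universe = tuple(BACKBONE_MARKERS + _PANEL_A_SPECIFIC + _PANEL_B_SPECIFIC + _PANEL_C_SPECIFIC)

    baseline, lineage_high, sd = 0.3, 4.0, 0.25
    activation_base = 0.8  # monocyte/PMN resting level of the HIV-shifted markers
    shift = 2.2

    def pop(name, highs, hea, hiv, shifted=False):
        mean = {m: baseline for m in universe}
        mean["CD45"] = 4.0  # pan-leukocyte
        mean.update(highs)
        if shifted:
            for m in HIV_SHIFTED_MARKERS:
                mean[m] = activation_base
        shifts = {"HIV": {m: shift for m in HIV_SHIFTED_MARKERS}} if shifted else {}
        return PopulationSpec(
            name=name,
            mean=mean,
            sd={m: sd for m in universe},
            abundance={"HEA": hea, "HIV": hiv},
            condition_shifts=shifts,
        )

    populations = (
        pop("T cell", {"CD3": lineage_high, "CD4": 2.5, "CD8a": 1.5, "CD45RA": 2.0}, 0.28, 0.24),
        pop("B cell", {"CD19": lineage_high, "HLADR": lineage_high, "CD23": 1.5}, 0.08, 0.08),
        pop("NK cell", {"CD16": lineage_high, "GranzymeB": lineage_high,
                        "GranzymeA": 3.0, "CD56": 3.5, "Perforin": 3.0}, 0.07, 0.07),
        pop("Monocyte", {"CD14": lineage_high, "HLADR": lineage_high, "CD11c": lineage_high,
                         "MCP-1": 1.0}, 0.12, 0.14, shifted=True),
        pop("mDC", {"CD11c": lineage_high, "HLADR": lineage_high, "CD1c": 3.5}, 0.03, 0.03),
        pop("pDC", {"CD123": lineage_high, "HLADR": lineage_high}, 0.01, 0.01),
        pop("PMN", {"CD66": lineage_high, "CD16": 2.5}, 0.38, 0.40, shifted=True),
        pop("Basophil", {"CD123": lineage_high, "CD62L": 1.5}, 0.03, 0.03),
    )
    individuals = (
        ("HEA-1", "HEA"), ("HEA-2", "HEA"), ("HEA-3", "HEA"),
        ("PAT-1", "HIV"), ("PAT-2", "HIV"), ("PAT-3", "HIV"),
    )
    return CohortSpec(
        populations=populations,
        marker_universe=universe,
        panels=panels,
        individuals=individuals,
        n_events=n_events,
        backbone_noise_sd=0.05,
        seed=seed,
    )
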