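"""Synthetic study generator: per-cell ground truth and noisy TCSPC histograms.

Emulates the live-cell FLIM-FRET study design this package analyzes: a set of
transfection conditions (donor-only control, donor + acceptor for wild-type
and mutant transcription-factor pairs, a free-acceptor negative control),
each measured over several independent experiments with tens of cells per
condition.  Each cell draws its own unquenched-donor (UD) lifetime,
quenched-donor (QD) lifetime, donor-acceptor binding fraction and donor /
acceptor expression intensities; a TCSPC histogram is then sampled photon by
photon (multinomially) from the forward model of :mod:`flimfret.tcspc`.

Between-cell distribution families (truncated Normal lifetimes, logit-Normal
binding, lognormal intensities) are this package's modeling choice; only the
wild-type lifetime summaries (2.75 +/- 0.14 ns UD, 1.10 +/- 0.20 ns QD) are
anchored to reported measurements.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from .errors import ConfigError, DesignSizeWarning
from .tcspc import (
    AcquisitionConfig,
    DecayModel,
    ExponentialComponent,
    TCSPCHistogram,
    expected_counts,
)

__all__ = [
    "ConditionDesign",
    "CellTruth",
    "draw_cell",
    "simulate_histogram",
    "simulate_experiment",
    "paper_design",
    "MIN_CELLS_PER_CONDITION",
]

#: Study-scale minimum number of cells per condition.
MIN_CELLS_PER_CONDITION = 38

#: Lower truncation of the UD lifetime distribution (ns).
_TAU_UD_FLOOR = 0.5
#: Lower truncation of the QD lifetime distribution (ns).
_TAU_QD_FLOOR = 0.1


@dataclass(frozen=True)
class ConditionDesign:
    """Population parameters of one experimental condition.

    ``binding_mean`` is the central binding fraction on the natural scale;
    ``binding_sd`` is the spread of the per-cell draw on the logit scale.
    Intensities are lognormal; an acceptor log-mean of ``None`` means no
    acceptor is expressed (donor-only).  ``ad_coupling`` > 0 makes the
    per-cell binding fraction increase logistically with the cell's
    log acceptor:donor ratio (the expression-stoichiometry confound);
    it is off by default.
    """

    name: str
    tau_ud_mean: float = 2.75
    tau_ud_sd: float = 0.14
    tau_qd_mean: float = 1.10
    tau_qd_sd: float = 0.20
    binding_mean: float = 0.5
    binding_sd: float = 0.5
    photons_per_cell: int = 100_000
    donor_intensity_logmean: float = 0.0
    donor_intensity_logsd: float = 0.4
    acceptor_intensity_logmean: Optional[float] = 0.0
    acceptor_intensity_logsd: float = 0.4
    compartment: str = "nuclear"
    n_cells: int = 14
    n_experiments: int = 3
    ad_coupling: float = 0.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("condition name must be non-empty")
        if self.n_cells < 1 or self.n_experiments < 1:
            raise ConfigError("n_cells and n_experiments must be >= 1")
        if not 0.0 <= self.binding_mean <= 1.0:
            raise ConfigError("binding_mean must be in [0, 1]")
        if self.binding_mean > 0 and self.tau_qd_mean >= self.tau_ud_mean:
            raise ConfigError(
                f"{self.name}: tau_qd_mean must be below tau_ud_mean "
                "when binding is present"
            )
        if self.photons_per_cell < 1:
            raise ConfigError("photons_per_cell must be >= 1")
        if self.n_cells * self.n_experiments < MIN_CELLS_PER_CONDITION:
            warnings.warn(
                f"condition {self.name!r}: "
                f"{self.n_cells * self.n_experiments} cells is below the "
                f"study-scale minimum of {MIN_CELLS_PER_CONDITION}",
                DesignSizeWarning,
                stacklevel=2,
            )

    @property
    def total_cells(self) -> int:
        return self.n_cells * self.n_experiments


@dataclass(frozen=True)
class CellTruth:
    """Ground-truth parameters of one simulated cell (= one ROI)."""

    roi_id: str
    condition: str
    compartment: str
    experiment_index: int
    true_tau_ud: float
    true_tau_qd: float
    true_binding: float
    photons: int
    donor_intensity: float
    acceptor_intensity: float
    seed_used: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_binding <= 1.0:
            raise ConfigError("true_binding must be in [0, 1]")
        if self.true_binding > 0 and self.true_tau_qd >= self.true_tau_ud:
            raise ConfigError("true_tau_qd must be below true_tau_ud")


def _rng_for(master_seed: int, design_name: str, *indices: int) -> tuple[np.random.Generator, int]:
    """Deterministic per-cell RNG stream keyed by seed, condition and indices."""
    key = zlib.crc32(design_name.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), key, *map(int, indices)])
    seed_used = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
    return np.random.default_rng(ss), seed_used


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float = np.inf
) -> float:
    """Draw Normal(mean, sd) restricted to (low, high) by rejection."""
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low < x < high:
            return float(x)
    # Distribution mass almost entirely outside the window; clamp.
    return float(np.clip(mean, low + 1e-9, high - 1e-9 if np.isfinite(high) else mean))


def draw_cell(
    design: ConditionDesign,
    experiment_index: int,
    cell_index: int,
    master_seed: int,
) -> CellTruth:
    """Realize one cell's ground truth from the condition's population model.

    Fully deterministic in ``(master_seed, design.name, experiment_index,
    cell_index)``.  UD lifetime ~ Normal truncated at 0.5 ns; QD lifetime ~
    Normal truncated to (0.1 ns, UD); binding fraction ~ logit-Normal,
    optionally coupled to the cell's log A:D intensity ratio.
    """
    rng, seed_used = _rng_for(master_seed, design.name, experiment_index, cell_index)

    tau_ud = _truncated_normal(rng, design.tau_ud_mean, design.tau_ud_sd, _TAU_UD_FLOOR)
    tau_qd = _truncated_normal(
        rng, design.tau_qd_mean, design.tau_qd_sd, _TAU_QD_FLOOR, tau_ud
    )
    donor = float(rng.lognormal(design.donor_intensity_logmean, design.donor_intensity_logsd))
    if design.acceptor_intensity_logmean is None:
        acceptor = 0.0
    else:
        acceptor = float(
            rng.lognormal(design.acceptor_intensity_logmean, design.acceptor_intensity_logsd)
        )

    if design.binding_mean <= 0.0 or acceptor == 0.0:
        binding = 0.0
    elif design.binding_mean >= 1.0:
        binding = 1.0
    else:
        z = float(logit(design.binding_mean))
        if design.ad_coupling != 0.0:
            # Center the coupling on the design's expected log A:D ratio so
            # switching it on does not shift the population mean binding.
            expected_log_ratio = (
                design.acceptor_intensity_logmean - design.donor_intensity_logmean
            )
            z += design.ad_coupling * (np.log(acceptor / donor) - expected_log_ratio)
        if design.binding_sd > 0:
            z += design.binding_sd * rng.standard_normal()
        binding = float(expit(z))

    roi_id = f"{design.name}:{design.compartment}:e{experiment_index}:c{cell_index}"
    return CellTruth(
        roi_id=roi_id,
        condition=design.name,
        compartment=design.compartment,
        experiment_index=experiment_index,
        true_tau_ud=tau_ud,
        true_tau_qd=tau_qd,
        true_binding=binding,
        photons=design.photons_per_cell,
        donor_intensity=donor,
        acceptor_intensity=acceptor,
        seed_used=seed_used,
    )


def decay_model_for(truth: CellTruth, background_fraction: float) -> DecayModel:
    """Two-species donor decay for a cell: fractions (1-B, B) at (UD, QD)."""
    b = truth.true_binding
    if b <= 0.0:
        comps = (ExponentialComponent(1.0, truth.true_tau_ud),)
    elif b >= 1.0:
        comps = (ExponentialComponent(1.0, truth.true_tau_qd),)
    else:
        comps = (
            ExponentialComponent(1.0 - b, truth.true_tau_ud),
            ExponentialComponent(b, truth.true_tau_qd),
        )
    return DecayModel(components=comps, background_fraction=background_fraction)


def simulate_histogram(
    truth: CellTruth,
    config: AcquisitionConfig,
    rng: Optional[np.random.Generator] = None,
) -> TCSPCHistogram:
    """Sample a TCSPC histogram for one cell.

    Counts are multinomial over the normalized expected-counts shape, so they
    sum exactly to ``truth.photons``.  With no ``rng`` given, a deterministic
    stream derived from ``truth.seed_used`` is used.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([truth.seed_used, 1]))
    model = decay_model_for(truth, config.background_fraction)
    expect = expected_counts(model, config, total_photons=1.0, periodic_wrap=True)
    probs = expect / expect.sum()
    counts = rng.multinomial(truth.photons, probs)
    return TCSPCHistogram(
        counts=counts,
        config=config,
        roi_id=truth.roi_id,
        condition=truth.condition,
        compartment=truth.compartment,
        experiment_index=truth.experiment_index,
    )


def simulate_experiment(
    designs: Sequence[ConditionDesign],
    master_seed: int,
    config: Optional[AcquisitionConfig] = None,
) -> tuple[list[CellTruth], list[TCSPCHistogram]]:
    """Generate all cells and histograms for a list of condition designs.

    ROI ids are unique; the whole dataset is reproducible from
    ``master_seed`` alone (per-cell streams are independent of enumeration
    order).
    """
    names = [d.name + "/" + d.compartment for d in designs]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate condition (name, compartment) in designs")
    if config is None:
        config = AcquisitionConfig()
    truths: list[CellTruth] = []
    hists: list[TCSPCHistogram] = []
    for design in designs:
        for exp in range(design.n_experiments):
            for cell in range(design.n_cells):
                truth = draw_cell(design, exp, cell, master_seed)
                truths.append(truth)
                hists.append(simulate_histogram(truth, config))
    return truths, hists


def paper_design() -> list[ConditionDesign]:
    """Default study design: the seven-condition live-cell FRET layout.

    Wild-type donor+acceptor lifetimes follow the reported summaries
    (UD 2.75 +/- 0.14 ns, QD 1.10 +/- 0.20 ns).  Mutant binding levels are
    illustrative defaults (reduced binding for the dimerization mutants,
    higher extranuclear than nuclear binding for the NLS-deficient acceptor),
    and the free-acceptor negative control is a low-binding, wide-spread
    population.  3 experiments x 14 cells = 42 cells per condition.
    """
    return [
        ConditionDesign(
            name="donor_only",
            binding_mean=0.0,
            acceptor_intensity_logmean=None,
        ),
        ConditionDesign(name="WT+E47", binding_mean=0.50),
        ConditionDesign(
            name="A59T+E47", tau_qd_mean=1.25, binding_mean=0.35
        ),
        ConditionDesign(name="del+E47", binding_mean=0.25),
        ConditionDesign(
            name="del+E47dNLS", binding_mean=0.20, compartment="nuclear"
        ),
        ConditionDesign(
            name="del+E47dNLS",
            binding_mean=0.35,
            compartment="extranuclear",
            acceptor_intensity_logmean=0.4,
        ),
        ConditionDesign(
            name="neg_ctrl_freeRuby",
            binding_mean=0.05,
            binding_sd=1.0,
            tau_qd_sd=0.40,
        ),
    ]
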