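"""Synthetic degradome generator: fragmentation, fractionation, measurement.

Emulates the experimental designs the pipeline is meant to analyse: a mixed
cellular RNA pool (tRNA, 18S/28S rRNA, mRNA, mitochondrial tRNA) undergoes
random endonucleolytic cleavage, the resulting fragment pool is gel-
fractionated into a tRNA-size window (60-75 nt) and an RNA-fragment window
(15-50 nt), and each window is "measured" as noisy two-channel MRM peak
areas plus canonical-nucleoside UV areas — with full ground truth retained.

Model
-----
Cuts are placed as a Poisson process along each molecule.  The per-nt cut
density of species *s* at time *t* is::

    u_s(t) = susceptibility_s * (baseline + rate * t [+ freeze_thaw_extra])

``baseline`` is the isolation-induced cut density present at t = 0 (so the
fragment windows are populated from the onset), ``rate`` is tissue-specific
(liver far faster than brain), and ``susceptibility`` expresses that compact,
protein-bound tRNA is cleaved far more slowly than exposed rRNA/mRNA.
Modification residues are assumed uniformly distributed along each molecule,
so a window's expected modification content is (window mass of species) x
(per-nt modification density), summed over species.

The per-species modification densities are seeded from the packaged
absolute-quantification reference matrix, with literature-style densities
for species not quantified there; Am and m6,6A densities are zero in tRNA
by construction — their appearance in a tRNA-size window is entirely
degradation-derived, which is what the QC markers exploit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import iodata
from .iodata import (
    PeakRecord,
    PeakTable,
    SampleMeta,
    TransitionTable,
    UVRecord,
)
from .quantify import Chromatogram

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesProfile",
    "NoiseModel",
    "DegradomeConfig",
    "SimResult",
    "FragmentDistribution",
    "fragment_distribution",
    "fractionate",
    "integrity_score",
    "expected_mass_in_window",
    "expected_window_masses",
    "expected_integrity",
    "measure",
    "simulate_study",
    "fit_cleavage_rate",
    "default_config",
    "default_species",
    "synthesize_chromatogram",
    "SCENARIOS",
]

#: Gel windows in nt, inclusive.
DEFAULT_WINDOWS: dict[str, tuple[int, int]] = {"tRNA": (60, 75), "RF": (15, 50)}

_T2_COLUMN = {"tRNA": "tRNA #1", "rRNA18S": "18S rRNA #1",
              "rRNA28S": "28S rRNA #1", "mRNA": "mRNA #1"}

# Reference values are % of the adenosine UV signal; with A ~ 1/4 of
# residues, value/400 approximates modified residues per nt.
_T2_TO_DENSITY = 1.0 / 400.0

# Densities (per nt) for panel modifications absent from the packaged
# reference matrix; literature-magnitude choices, zero where a species is
# not known to carry the modification.
_EXTRA_DENSITY: dict[str, dict[str, float]] = {
    "tRNA": {"D": 2.0 / 75, "Psi": 3.0 / 75, "m1A": 0.8 / 75, "Tm": 0.2 / 75,
             "mcm5U": 0.3 / 75, "s2U": 0.15 / 75, "s2C": 0.1 / 75, "Q": 0.3 / 75},
    "rRNA18S": {"Psi": 0.02, "m1A": 0.0005},
    "rRNA28S": {"Psi": 0.015, "m1A": 0.001},
    "mRNA": {},
}

#: Tissue-specific multipliers on tRNA-core modification densities; what the
#: brain-tissue discrimination scenario is built on.
TISSUE_TRNA_MULTIPLIERS: dict[str, dict[str, float]] = {
    "cortex": {},
    "cerebellum": {"m5U": 1.35, "m1G": 1.30, "t6A": 0.75, "I": 0.70,
                   "m3C": 1.25, "D": 1.20},
    "hippocampus": {"m2,2G": 1.35, "m2G": 1.30, "Q": 1.40, "i6A": 0.70,
                    "Tm": 1.30, "m1A": 0.75},
}


@dataclass(frozen=True)
class SpeciesProfile:
    """One RNA species in the pool."""

    name: str
    length: int
    mass_fraction: float
    susceptibility: float
    mod_density: Mapping[str, float]  # expected modified residues per nt

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1 nt")
        if not 0 <= self.mass_fraction <= 1:
            raise ValueError("mass fraction must be in [0, 1]")
        bad = [m for m, d in self.mod_density.items() if d < 0]
        if bad:
            raise ValueError(f"negative modification density for {bad}")
        if self.name in ("tRNA", "mito_tRNA"):
            for marker in ("Am", "m6,6A"):
                if self.mod_density.get(marker, 0.0) != 0.0:
                    raise ValueError(f"{marker} density must be 0 in {self.name}")


def default_species(
    scenario: str = "postmortem",
    tissue: str | None = None,
) -> list[SpeciesProfile]:
    """The default five-species pool, densities seeded from the reference matrix.

    ``susceptibility`` of the tRNA-sized species is 0.05 post mortem
    (structured, protein-bound RNA inside dying cells) and 0.3 in vitro
    (deproteinised but still base-paired); rRNA and mRNA are 1.0.
    """
    table2 = iodata.load_table2().values
    trna_protect = 0.3 if scenario == "invitro" else 0.05
    mult = TISSUE_TRNA_MULTIPLIERS.get(tissue or "", {})

    def densities(species: str) -> dict[str, float]:
        dens: dict[str, float] = {}
        col = _T2_COLUMN[species]
        for mod in table2.index:
            dens[mod] = float(table2.loc[mod, col]) * _T2_TO_DENSITY
        dens.update(_EXTRA_DENSITY[species])
        if species == "tRNA":
            # rRNA-derived contamination in the reference tRNA column, not
            # tRNA chemistry: these must be zero for the markers to work.
            dens["Am"] = dens["m6,6A"] = dens["m3U"] = 0.0
            for mod, f in mult.items():
                if mod in dens:
                    dens[mod] *= f
        return dens

    trna = densities("tRNA")
    mito = {m: 0.8 * d for m, d in trna.items()}
    mito.update({"ms2i6A": 0.85 / 70, "Q": 0.4 / 70, "m2A": 0.15 / 70,
                 "m1A": 1.0 / 70, "Am": 0.0, "m6,6A": 0.0, "m3U": 0.0})
    return [
        SpeciesProfile("tRNA", 75, 0.10, trna_protect, trna),
        SpeciesProfile("mito_tRNA", 70, 0.03, trna_protect, mito),
        SpeciesProfile("rRNA18S", 1870, 0.25, 1.0, densities("rRNA18S")),
        SpeciesProfile("rRNA28S", 4718, 0.57, 1.0, densities("rRNA28S")),
        SpeciesProfile("mRNA", 2000, 0.05, 1.0, densities("mRNA")),
    ]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings (lognormal sigmas unless stated).

    ``rf_heterogeneity_sd`` applies to RF-window light-channel areas only,
    emulating the incoherent behaviour of heterogeneous fragment pools in
    that window.  Gains convert per-nt modification concentration to MS
    area and injected amount to UV area; their absolute scale is arbitrary.
    """

    peak_area_sd: float = 0.08
    c13_sd: float = 0.05
    uv_sd: float = 0.03
    injection_sd: float = 0.10
    snr_floor: float = 0.15
    snr_floor_sd: float = 0.20
    rf_heterogeneity_sd: float = 0.35
    ms_gain: float = 1.0e6
    istd_level: float = 5.0e4
    uv_gain: float = 4.0e4
    istd_uv_response_per_ng: float = 0.0

    @classmethod
    def zero(cls) -> "NoiseModel":
        """Noise-free variant (for end-to-end identity checks)."""
        return cls(peak_area_sd=0.0, c13_sd=0.0, uv_sd=0.0, injection_sd=0.0,
                   snr_floor_sd=0.0, rf_heterogeneity_sd=0.0)


@dataclass(frozen=True)
class DegradomeConfig:
    """Full study design for one simulation run."""

    scenario: str
    tissues: Mapping[str, float]  # tissue -> cleavage rate (per nt per hour)
    timepoints: tuple[float, ...] = (0.0, 1.0, 8.0, 24.0)
    replicates: int = 4
    windows: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS))
    species: Mapping[str, Sequence[SpeciesProfile]] | None = None  # per tissue
    baseline_cut_density: float = 5.0e-5  # per nt, isolation-induced, at t=0
    freeze_thaw_extra: Mapping[str, float] = field(default_factory=dict)
    include_unfrozen_t0: bool = True
    frozen: bool = True
    noise: NoiseModel = field(default_factory=NoiseModel)
    label_threshold: float = 2.0
    max_cut_draws: float = 2.0e6  # molecule count adapts to keep work bounded
    seed: int = 0

    def __post_init__(self):
        for name, (lo, hi) in self.windows.items():
            if not 1 <= lo <= hi:
                raise ValueError(f"window {name}: bad bounds [{lo}, {hi}]")
        spans = sorted(self.windows.values())
        for (l1, h1), (l2, h2) in zip(spans, spans[1:]):
            if l2 <= h1:
                raise ValueError("fraction windows must be disjoint")
        if any(r < 0 for r in self.tissues.values()):
            raise ValueError("cleavage rates must be >= 0")
        if self.baseline_cut_density < 0:
            raise ValueError("baseline cut density must be >= 0")

    def species_for(self, tissue: str) -> list[SpeciesProfile]:
        if self.species is not None and tissue in self.species:
            return list(self.species[tissue])
        return default_species(self.scenario, tissue)


SCENARIOS = ("invitro", "postmortem", "braintissues")


def default_config(scenario: str, seed: int = 0) -> DegradomeConfig:
    """Study-design presets mirroring the three experimental settings."""
    if scenario == "invitro":
        return DegradomeConfig(
            scenario="invitro",
            tissues={"liver": 0.2},
            timepoints=(0.0, 5 / 60, 15 / 60, 30 / 60),
            replicates=3,
            include_unfrozen_t0=False,
            frozen=False,
            seed=seed,
        )
    if scenario == "postmortem":
        return DegradomeConfig(
            scenario="postmortem",
            tissues={"liver": 7.0e-5, "brain": 2.0e-6},
            timepoints=(0.0, 1.0, 8.0, 24.0),
            replicates=4,
            freeze_thaw_extra={"liver": 2.0e-5, "brain": 0.0},
            include_unfrozen_t0=True,
            seed=seed,
        )
    if scenario == "braintissues":
        return DegradomeConfig(
            scenario="braintissues",
            tissues={"cortex": 2.0e-6, "cerebellum": 2.0e-6, "hippocampus": 2.0e-6},
            timepoints=(0.0,),
            replicates=4,
            include_unfrozen_t0=False,
            frozen=False,
            seed=seed,
        )
    raise ValueError(f"unknown scenario {scenario!r}; pick one of {SCENARIOS}")


# ---------------------------------------------------------------------------
# fragmentation


@dataclass(frozen=True)
class FragmentDistribution:
    """Fragment-length mass histogram for one species.

    ``mass_nt[l]`` is the total nt mass found in fragments of length ``l``
    across all simulated molecules (integer, so mass conservation is exact:
    ``mass_nt.sum() == n_molecules * length``).
    """

    length: int
    n_molecules: int
    mass_nt: np.ndarray  # shape (length + 1,), int64

    @property
    def mass_per_molecule(self) -> np.ndarray:
        """Average nt mass per molecule at each fragment length (sums to L)."""
        return self.mass_nt / self.n_molecules

    def window_mass_fraction(self, lo: int, hi: int) -> float:
        hi = min(hi, self.length)
        if lo > self.length:
            return 0.0
        return float(self.mass_nt[lo:hi + 1].sum() / self.mass_nt.sum())


def fragment_distribution(
    length: int,
    expected_cuts: float,
    rng: np.random.Generator | int,
    n_molecules: int = 100_000,
) -> FragmentDistribution:
    """Fragment ``n_molecules`` chains of ``length`` nt by random cleavage.

    Each molecule receives ``Poisson(expected_cuts)`` cuts at uniform random
    internal bonds (coincident draws collapse); fragment lengths are the
    gaps.  Total mass is conserved exactly.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if expected_cuts < 0:
        raise ValueError("expected cut count must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    L = int(length)
    n = int(n_molecules)
    mass = np.zeros(L + 1, dtype=np.int64)
    if L == 1 or expected_cuts == 0:
        mass[L] = n * L
        return FragmentDistribution(L, n, mass)
    counts = rng.poisson(expected_cuts, size=n)
    cut_mols = np.flatnonzero(counts)
    # molecules without cuts stay intact; no need to materialise them
    mass[L] += np.int64(n - cut_mols.size) * L
    if cut_mols.size == 0:
        return FragmentDistribution(L, n, mass)
    counts = counts[cut_mols]
    total = int(counts.sum())
    cuts = rng.integers(1, L, size=total, dtype=np.int64)
    mol_idx = np.arange(cut_mols.size, dtype=np.int64)
    mol_of_cut = np.repeat(mol_idx, counts)
    # endpoints 0 and L of every cut molecule, all on one global axis;
    # sorting then differencing yields every fragment length (inter-molecule
    # gaps and coincident cuts appear as zero-length diffs and drop out)
    endpoints = np.concatenate([
        mol_idx * L,
        (mol_idx + 1) * L,
        mol_of_cut * L + cuts,
    ])
    endpoints.sort(kind="stable")
    lengths = np.diff(endpoints)
    lengths = lengths[lengths > 0]
    np.add.at(mass, lengths, lengths)
    assert mass.sum() == np.int64(n) * L
    return FragmentDistribution(L, n, mass)


def _adaptive_n_molecules(expected_cuts: float, budget: float) -> int:
    return int(np.clip(budget / (expected_cuts + 2.0), 2000, 400_000))


def fractionate(
    distributions: Mapping[str, FragmentDistribution],
    profiles: Mapping[str, SpeciesProfile],
    windows: Mapping[str, tuple[int, int]] = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Per-window, per-species mass (units: fraction of total pool mass).

    A species' contribution to a window is its pool mass fraction times the
    fraction of its own mass lying at fragment lengths inside the window.
    """
    rows = {}
    for wname, (lo, hi) in windows.items():
        rows[wname] = {
            sp: profiles[sp].mass_fraction * dist.window_mass_fraction(lo, hi)
            for sp, dist in distributions.items()
        }
    return pd.DataFrame(rows).T  # windows x species


def integrity_score(
    distributions: Mapping[str, FragmentDistribution],
    profiles: Mapping[str, SpeciesProfile],
) -> float:
    """In-silico integrity proxy on the 1-10 scale.

    1 + 9 x (pool mass fraction residing in fragments of at least half the
    parent species' full length).  An intact pool scores 10, a fully
    atomised one 1; the score decreases monotonically with cleavage.  This
    is an explicit proxy with the same orientation as electrophoretic RNA
    integrity numbers, not a reimplementation of any vendor algorithm.
    """
    frac = 0.0
    total = 0.0
    for sp, dist in distributions.items():
        half = int(np.ceil(dist.length / 2.0))
        w = profiles[sp].mass_fraction
        frac += w * dist.window_mass_fraction(half, dist.length)
        total += w
    return 1.0 + 9.0 * (frac / total if total > 0 else 0.0)


# ---------------------------------------------------------------------------
# analytic expectations (ground-truth labels and rate fitting)


def _int_l_exp(a: float, b: float, u: float) -> float:
    """integral of l * exp(-u l) dl over [a, b]."""
    if u == 0:
        return (b * b - a * a) / 2.0
    def F(l):  # antiderivative
        return -(l / u + 1.0 / u**2) * np.exp(-u * l)
    return F(b) - F(a)


def _int_l2_exp(a: float, b: float, u: float) -> float:
    """integral of l^2 * exp(-u l) dl over [a, b]."""
    if u == 0:
        return (b**3 - a**3) / 3.0
    def F(l):
        return -(l * l / u + 2.0 * l / u**2 + 2.0 / u**3) * np.exp(-u * l)
    return F(b) - F(a)


def expected_mass_in_window(length: int, u: float, lo: float, hi: float) -> float:
    """Expected fraction of a molecule's mass at fragment lengths in [lo, hi].

    Continuous Poisson-cleavage expectation: internal fragments of length l
    occur with density u^2 (L - l) e^{-u l}, the two end fragments with
    density u e^{-u l}, and the molecule stays intact with probability
    e^{-u L}.
    """
    L = float(length)
    hi = min(float(hi), L)
    lo = float(lo)
    if lo > L or hi < lo:
        return 0.0
    if u == 0:
        return 1.0 if lo <= L <= hi else 0.0
    i1 = _int_l_exp(lo, hi, u)
    i2 = _int_l2_exp(lo, hi, u)
    frac = (2.0 * u * i1 + u * u * (L * i1 - i2)) / L
    if lo <= L <= hi:
        frac += np.exp(-u * L)
    return float(frac)


def expected_window_masses(
    profiles: Sequence[SpeciesProfile],
    cut_density: float,
    windows: Mapping[str, tuple[int, int]] = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Analytic counterpart of simulate-then-:func:`fractionate`."""
    rows = {}
    for wname, (lo, hi) in windows.items():
        rows[wname] = {
            p.name: p.mass_fraction * expected_mass_in_window(
                p.length, p.susceptibility * cut_density, lo, hi)
            for p in profiles
        }
    return pd.DataFrame(rows).T


def expected_integrity(profiles: Sequence[SpeciesProfile], cut_density: float) -> float:
    """Analytic expectation of :func:`integrity_score`."""
    frac = 0.0
    for p in profiles:
        u = p.susceptibility * cut_density
        frac += p.mass_fraction * expected_mass_in_window(
            p.length, u, np.ceil(p.length / 2.0), p.length)
    return 1.0 + 9.0 * frac


def window_concentrations(
    window_masses: Mapping[str, float],
    profiles: Mapping[str, SpeciesProfile],
    modifications: Iterable[str],
) -> dict[str, float]:
    """Per-nt modification concentration of a window's pooled RNA."""
    total = float(sum(window_masses.values()))
    out = {}
    for mod in modifications:
        if total <= 0:
            out[mod] = 0.0
            continue
        raw = sum(window_masses[sp] * profiles[sp].mod_density.get(mod, 0.0)
                  for sp in window_masses)
        out[mod] = raw / total
    return out


# ---------------------------------------------------------------------------
# measurement


def measure(
    window_masses: Mapping[str, float],
    profiles: Mapping[str, SpeciesProfile],
    table: TransitionTable,
    noise: NoiseModel,
    rng: np.random.Generator,
    sample_id: str,
    fraction: str = "tRNA",
) -> tuple[list[PeakRecord], UVRecord, dict[str, float]]:
    """Turn a window composition into noisy MRM + UV observations.

    The light-channel area is gain x (per-nt modification concentration of
    the window) x injection scale, with multiplicative lognormal noise (plus
    the RF-heterogeneity term in the RF window).  The heavy channel sits at
    a constant internal-standard level independent of the sample load.  UV
    canonical areas split the injected amount into four equal bases, plus
    any configured internal-standard UV response.  Returns the records, the
    UV record and the true (noise-free) concentrations.
    """

    def logn(sd: float) -> float:
        return float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0

    truth = window_concentrations(window_masses, profiles, table.modifications)
    injection = logn(noise.injection_sd)
    records: list[PeakRecord] = []
    for mod in table.modifications:
        area12 = noise.ms_gain * truth[mod] * injection * logn(noise.peak_area_sd)
        if fraction == "RF":
            area12 *= logn(noise.rf_heterogeneity_sd)
        floor = noise.snr_floor * logn(noise.snr_floor_sd)
        snr = area12 / floor if floor > 0 else 0.0
        records.append(PeakRecord(sample_id, mod, "C12", area12, snr))
        if mod in table.silis_members:
            area13 = noise.istd_level * logn(noise.c13_sd)
            records.append(PeakRecord(sample_id, mod, "C13", area13, 50.0))
    base_area = (noise.uv_gain / 4.0) * injection
    istd_uv = noise.istd_uv_response_per_ng * 50.0
    uv = UVRecord(
        sample_id,
        *(base_area * logn(noise.uv_sd) + istd_uv for _ in range(4)),
    )
    return records, uv, truth


def synthesize_chromatogram(
    ret_time: float,
    auc: float,
    rng: np.random.Generator,
    peak_width_min: float = 0.15,
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    span: tuple[float, float] = (0.0, 30.0),
    dt: float = 0.01,
) -> Chromatogram:
    """A Gaussian peak of the given analytic area on a uniform time grid."""
    t = np.arange(span[0], span[1] + dt / 2, dt)
    y = baseline + auc / (peak_width_min * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((t - ret_time) / peak_width_min) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    return Chromatogram(t, np.clip(y, 0.0, None))


# ---------------------------------------------------------------------------
# full study


@dataclass
class SimResult:
    """Everything a downstream pipeline needs, plus the ground truth."""

    config: DegradomeConfig
    peaks: PeakTable
    uv: dict[str, UVRecord]
    meta: dict[str, SampleMeta]
    ground_truth: dict[str, dict]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "peaks": out / "peaks.csv",
            "uv": out / "uv_areas.csv",
            "meta": out / "samples.csv",
            "ground_truth": out / "ground_truth.json",
        }
        iodata.write_peak_report(self.peaks, paths["peaks"])
        iodata.write_uv_areas(self.uv, paths["uv"])
        iodata.write_sample_meta(self.meta, paths["meta"])
        paths["ground_truth"].write_text(
            json.dumps(self.ground_truth, indent=1, sort_keys=True))
        return paths


def _simulate_sample(
    profiles: Sequence[SpeciesProfile],
    cut_density: float,
    config: DegradomeConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, FragmentDistribution], pd.DataFrame, float]:
    dists = {}
    for p in profiles:
        lam = p.susceptibility * cut_density * max(p.length - 1, 1)
        n_mol = _adaptive_n_molecules(lam, config.max_cut_draws)
        dists[p.name] = fragment_distribution(p.length, lam, rng, n_mol)
    prof_map = {p.name: p for p in profiles}
    masses = fractionate(dists, prof_map, config.windows)
    score = integrity_score(dists, prof_map)
    return dists, masses, score


def simulate_study(
    config: DegradomeConfig,
    table: TransitionTable | None = None,
    out_dir: str | Path | None = None,
) -> SimResult:
    """Run the full study design and emit per-sample measurements.

    Deterministic given ``config.seed``.  Sample ids follow
    ``{tissue}_t{time}h_r{replicate}[_unfrozen]_{window}``; each physical
    sample is fragmented once and measured in every gel window.
    """
    if table is None:
        table = iodata.load_table1()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    records: list[PeakRecord] = []
    uv: dict[str, UVRecord] = {}
    meta: dict[str, SampleMeta] = {}
    truth: dict[str, dict] = {}

    designs: list[tuple[float, bool]] = [(t, config.frozen) for t in config.timepoints]
    if config.include_unfrozen_t0 and config.frozen:
        designs.insert(0, (0.0, False))

    for tissue, rate in config.tissues.items():
        profiles = config.species_for(tissue)
        prof_map = {p.name: p for p in profiles}
        # pristine reference: expected composition at the isolation baseline
        ref = expected_window_masses(profiles, config.baseline_cut_density,
                                     config.windows)
        ref_conc = {w: window_concentrations(ref.loc[w].to_dict(), prof_map,
                                             table.modifications)
                    for w in config.windows}
        for time_h, frozen in designs:
            density = config.baseline_cut_density + rate * time_h
            if frozen:
                density += config.freeze_thaw_extra.get(tissue, 0.0)
            for rep in range(1, config.replicates + 1):
                dists, masses, score = _simulate_sample(profiles, density, config, rng)
                stem = f"{tissue}_t{time_h:g}h_r{rep}" + ("" if frozen else "_unfrozen")
                for window in config.windows:
                    sample_id = f"{stem}_{window}"
                    wmass = masses.loc[window].to_dict()
                    recs, uvrec, conc = measure(
                        wmass, prof_map, table, config.noise, rng,
                        sample_id, fraction=window)
                    records.extend(recs)
                    uv[sample_id] = uvrec
                    meta[sample_id] = SampleMeta(
                        sample_id, tissue, window, time_h, str(rep), frozen)
                    folds = [conc[m] / ref_conc[window][m]
                             for m in ("m6,6A", "Am")
                             if ref_conc[window][m] > 0 and window == "tRNA"]
                    index_truth = float(np.exp(np.mean(np.log(folds)))) if folds else None
                    truth[sample_id] = {
                        "tissue": tissue, "time_h": time_h, "replicate": rep,
                        "frozen": frozen, "fraction": window,
                        "cut_density": density,
                        "window_masses": {k: float(v) for k, v in wmass.items()},
                        "true_concentration": {k: float(v) for k, v in conc.items()},
                        "integrity": float(score),
                        "index_truth": index_truth,
                        "degraded": (bool(index_truth > config.label_threshold)
                                     if index_truth is not None else None),
                    }
    result = SimResult(config, PeakTable(records), uv, meta, truth)
    if out_dir is not None:
        result.write(out_dir)
    return result


def fit_cleavage_rate(
    times: Sequence[float],
    scores: Sequence[float],
    profiles: Sequence[SpeciesProfile],
    baseline_cut_density: float = 5.0e-5,
    extra_cut_density: float = 0.0,
    grid: np.ndarray | None = None,
) -> float:
    """Recover a cleavage rate from an integrity-score time course.

    Least-squares grid search of the analytic integrity expectation
    ``expected_integrity(baseline + extra + rate * t)`` against the observed
    scores, with one local refinement pass around the best coarse rate.
    """
    times = np.asarray(times, float)
    scores = np.asarray(scores, float)
    if times.shape != scores.shape or times.size < 2:
        raise ValueError("need matching time/score vectors with >= 2 points")

    def sse(rate: float) -> float:
        pred = np.array([
            expected_integrity(profiles,
                               baseline_cut_density + extra_cut_density + rate * t)
            for t in times
        ])
        return float(((pred - scores) ** 2).sum())

    if grid is None:
        grid = np.logspace(-8, -1, 141)
    coarse = min(grid, key=sse)
    fine = coarse * np.logspace(-0.35, 0.35, 101)
    return float(min(fine, key=sse))
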