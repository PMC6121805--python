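"""Individual-based forward simulation of a 1D deme chain.

Diploids live in a chain of 1 m demes (152 in the study configuration)
with a habitat switch after deme 85.  Each generation: offspring are
produced within each deme by sampling two parents with probability
proportional to viability fitness in the parent's current deme, gametes
are transmitted Mendelian-fashion, offspring displace by a zero-mean
Gaussian (SD ``sigma`` metres, reflected at the chain ends) and are binned
to demes, and every deme is regulated back to exactly N individuals.

Selected loci (n = 200 in the study configuration) favour allele 1 on the
wave side of the switch and allele 0 on the crab side, with multiplicative
fitness across loci, additive within-locus effects, and a per-locus
coefficient calibrated so that the fitness gap between fully matched and
fully mismatched multilocus homozygotes equals the total selection
coefficient s (0.7).  Neutral loci are unlinked and unselected but share
the pedigree, so they experience the multilocus barrier to gene flow.

The default parameter values are the study conditions; ``sigma`` in
{1.09, 1.46, 1.70} and N in {50, 100, 200} span the sensitivity sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._simkernel import run_kernel, unpack_genotypes
from .exceptions import ConfigurationError, SimulationFailureError

__all__ = [
    "SimulationConfig",
    "SimOutput",
    "SamplingProfile",
    "SampledTransect",
    "run_simulation",
    "sample_transect",
    "default_study_profile",
    "profile_cline_center",
    "profile_cline_width",
]


@dataclass
class SimulationConfig:
    n_demes: int = 152
    deme_width: float = 1.0  # metres
    habitat_switch_after_deme: int = 85  # demes 1..85 are Crab habitat
    n_per_deme: int = 100
    sigma: float = 1.46  # dispersal SD, metres
    s_total: float = 0.7
    n_selected: int = 200
    n_neutral: int = 500
    generations: int = 4000
    model: str = "primary_divergence"  # or "secondary_contact"
    mutation_rate: float = 0.0  # per-allele per-generation flip probability
    thin: int = 50  # record allele counts every `thin` generations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_demes <= 0 or self.n_per_deme <= 0 or self.generations < 0:
            raise ConfigurationError("counts must be positive")
        if self.n_selected < 0 or self.n_neutral < 0:
            raise ConfigurationError("locus counts must be non-negative")
        if self.n_selected + self.n_neutral == 0:
            raise ConfigurationError("at least one locus required")
        if not 0 <= self.habitat_switch_after_deme <= self.n_demes:
            raise ConfigurationError("habitat switch outside the deme chain")
        if self.model not in ("primary_divergence", "secondary_contact"):
            raise ConfigurationError(f"unknown model {self.model!r}")
        if self.sigma < 0 or not 0 <= self.s_total < 1:
            raise ConfigurationError("sigma >= 0 and 0 <= s_total < 1 required")

    @property
    def n_loci(self) -> int:
        return self.n_selected + self.n_neutral

    @property
    def s_per_locus(self) -> float:
        """Per-locus coefficient: 1 - (1 - s_total)^(1/n_selected)."""
        if self.n_selected == 0 or self.s_total == 0:
            return 0.0
        return 1.0 - (1.0 - self.s_total) ** (1.0 / self.n_selected)


@dataclass
class SimOutput:
    """Thinned allele-frequency trajectories and final-generation genotypes."""

    config: SimulationConfig
    rec_gens: np.ndarray  # generations at which counts were recorded
    allele1_counts: np.ndarray  # (n_rec, n_demes, n_loci) uint32
    genotypes: np.ndarray  # (n_ind, n_loci) int8 dosage of allele 1
    deme: np.ndarray  # (n_ind,) final deme index
    selected: np.ndarray  # (n_loci,) bool

    def freq(self, record: int = -1) -> np.ndarray:
        """Per-deme allele-1 frequency at a recorded generation."""
        return self.allele1_counts[record] / (2.0 * self.config.n_per_deme)

    @property
    def final_freq(self) -> np.ndarray:
        return self.freq(-1)

    def save_npz(self, path) -> None:
        import dataclasses

        np.savez_compressed(
            path, rec_gens=self.rec_gens, allele1_counts=self.allele1_counts,
            genotypes=self.genotypes, deme=self.deme, selected=self.selected,
            config=np.array([repr(dataclasses.asdict(self.config))]),
        )


def _init_bitplanes(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n_demes * cfg.n_per_deme
    n_loci = cfg.n_loci
    nw = (n_loci + 63) // 64
    deme = np.repeat(np.arange(cfg.n_demes, dtype=np.int64), cfg.n_per_deme)
    # random bits at frequency 0.5, masked beyond the last locus
    a1 = rng.integers(0, 2 ** 64, size=(n, nw), dtype=np.uint64)
    a2 = rng.integers(0, 2 ** 64, size=(n, nw), dtype=np.uint64)
    tail_bits = nw * 64 - n_loci
    if tail_bits:
        keep = np.uint64((1 << (64 - tail_bits)) - 1) if tail_bits < 64 else np.uint64(0)
        a1[:, -1] &= keep
        a2[:, -1] &= keep
    if cfg.model == "secondary_contact" and cfg.n_selected > 0:
        # selected loci fixed for the locally favoured allele on each side
        sel_words = cfg.n_selected // 64
        rem = cfg.n_selected % 64
        wave = deme >= cfg.habitat_switch_after_deme
        for w in range(sel_words):
            a1[:, w] = np.where(wave, np.uint64(0xFFFFFFFFFFFFFFFF), np.uint64(0))
            a2[:, w] = a1[:, w]
        if rem:
            m = np.uint64((1 << rem) - 1)
            a1[:, sel_words] = np.where(wave, a1[:, sel_words] | m,
                                        a1[:, sel_words] & ~m)
            a2[:, sel_words] = np.where(wave, a2[:, sel_words] | m,
                                        a2[:, sel_words] & ~m)
    return a1, a2, deme


def run_simulation(config: SimulationConfig, seed: int | None = None) -> SimOutput:
    """Run the forward simulation; bit-identical for a given config + seed.

    Raises :class:`SimulationFailureError` if any deme loses all its
    individuals after dispersal.
    """
    cfg = config
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed)
    init_seed, kernel_seed = ss.spawn(2)
    rng = np.random.default_rng(init_seed)
    a1, a2, deme = _init_bitplanes(cfg, rng)
    n_loci = cfg.n_loci
    nw = a1.shape[1]

    selmask = np.zeros(nw, dtype=np.uint64)
    full = cfg.n_selected // 64
    selmask[:full] = np.uint64(0xFFFFFFFFFFFFFFFF)
    rem = cfg.n_selected % 64
    if rem:
        selmask[full] = np.uint64((1 << rem) - 1)

    s_loc = cfg.s_per_locus
    if s_loc > 0:
        log_f_het = float(np.log1p(-0.5 * s_loc))
        log_f_curv = float(np.log1p(-s_loc) - 2.0 * np.log1p(-0.5 * s_loc))
    else:
        log_f_het = 0.0
        log_f_curv = 0.0

    if cfg.generations == 0:
        rec_gens = np.zeros(0, dtype=np.int64)
    else:
        rec_gens = np.arange(cfg.thin, cfg.generations + 1, cfg.thin, dtype=np.int64)
        if len(rec_gens) == 0 or rec_gens[-1] != cfg.generations:
            rec_gens = np.append(rec_gens, cfg.generations)
    traj = np.zeros((len(rec_gens), cfg.n_demes, n_loci), dtype=np.uint32)

    out_a1 = np.empty_like(a1)
    out_a2 = np.empty_like(a2)
    out_deme = np.empty_like(deme)
    if cfg.generations == 0:
        out_a1[:], out_a2[:], out_deme[:] = a1, a2, deme
    else:
        kseed = int(kernel_seed.generate_state(1, dtype=np.uint32)[0])
        ext_gen, ext_deme = run_kernel(
            a1, a2, deme, out_a1, out_a2, out_deme, cfg.n_demes,
            cfg.n_per_deme, cfg.sigma, cfg.habitat_switch_after_deme,
            log_f_het, log_f_curv, selmask, cfg.n_selected, n_loci,
            cfg.generations, rec_gens, traj, cfg.mutation_rate, kseed,
        )
        if ext_gen >= 0:
            raise SimulationFailureError(int(ext_gen), int(ext_deme))

    genotypes = unpack_genotypes(out_a1, out_a2, n_loci)
    selected = np.zeros(n_loci, dtype=bool)
    selected[: cfg.n_selected] = True
    return SimOutput(
        config=cfg, rec_gens=rec_gens, allele1_counts=traj,
        genotypes=genotypes, deme=out_deme, selected=selected,
    )


# ---------------------------------------------------------------------------
# transect-style sampling of the final generation
# ---------------------------------------------------------------------------


@dataclass
class SamplingProfile:
    """Piecewise sampling density along the transect (metres).

    ``gaps`` are zero-weight intervals (intentional sampling breaks);
    ``troughs`` are (lo, hi, weight) intervals of reduced density (the
    natural low-density zone near the average cline center).
    """

    gaps: tuple = ()
    troughs: tuple = ()
    base_weight: float = 1.0

    def weight(self, positions_m: np.ndarray) -> np.ndarray:
        w = np.full(np.shape(positions_m), self.base_weight, dtype=float)
        for lo, hi in self.gaps:
            w[(positions_m >= lo) & (positions_m < hi)] = 0.0
        for lo, hi, wt in self.troughs:
            m = (positions_m >= lo) & (positions_m < hi)
            w[m] = np.minimum(w[m], wt)
        return w


def default_study_profile() -> SamplingProfile:
    """Study-like sampling: two intentional gaps plus a density trough
    just above the second habitat transition."""
    return SamplingProfile(gaps=((25.0, 35.0), (115.0, 125.0)),
                           troughs=((88.0, 94.0, 0.25),))


@dataclass
class SampledTransect:
    """Read-depth data for individuals sampled from a simulation."""

    positions: np.ndarray  # metres along the chain
    ref: np.ndarray  # (n_loci, n_ind) reference-allele (allele 0) reads
    alt: np.ndarray  # (n_loci, n_ind)
    genotypes: np.ndarray  # (n_ind, n_loci) true allele-1 dosage
    selected: np.ndarray
    individuals: np.ndarray  # indices into the simulation's final generation


def sample_transect(sim: SimOutput, profile: SamplingProfile | None = None,
                    n_individuals: int = 373, depth_mean: float = 20.0,
                    depth_dispersion: float | None = 5.0,
                    error_rate: float = 0.01,
                    seed: int | None = 0) -> SampledTransect:
    """Sample individuals along the chain and emit per-SNP read depths.

    Each final-generation individual receives a continuous position
    uniform within its deme; individuals are drawn without replacement
    with probability proportional to the profile weight at their position.
    Read depths are negative-binomial (mean ``depth_mean``, dispersion
    ``depth_dispersion``; constant depth if dispersion is None) and
    reference reads are binomial with genotype success probability
    mu_g = eps + (g_ref/2)(1 - 2 eps), where the reference allele is
    simulator allele 0.
    """
    if profile is None:
        profile = default_study_profile()
    cfg = sim.config
    rng = np.random.default_rng(seed)
    pos = (sim.deme + rng.uniform(size=len(sim.deme))) * cfg.deme_width
    w = profile.weight(pos)
    if (w > 0).sum() < n_individuals:
        raise ConfigurationError(
            "sampling profile leaves fewer weighted individuals than requested"
        )
    chosen = rng.choice(len(pos), size=n_individuals, replace=False, p=w / w.sum())
    chosen = chosen[np.argsort(pos[chosen], kind="stable")]
    g1 = sim.genotypes[chosen]  # allele-1 dosage
    g_ref = 2 - g1.astype(np.int64)
    mu = error_rate + (g_ref / 2.0) * (1.0 - 2.0 * error_rate)
    n, n_loci = g1.shape
    if depth_dispersion is None:
        depth = np.full((n, n_loci), int(round(depth_mean)), dtype=np.int64)
    elif depth_mean <= 0:
        depth = np.zeros((n, n_loci), dtype=np.int64)
    else:
        k = depth_dispersion
        depth = rng.negative_binomial(k, k / (k + depth_mean), size=(n, n_loci))
    ref = rng.binomial(depth, mu)
    alt = depth - ref
    return SampledTransect(
        positions=pos[chosen], ref=ref.T.copy(), alt=alt.T.copy(),
        genotypes=g1, selected=sim.selected.copy(), individuals=chosen,
    )


# ---------------------------------------------------------------------------
# cheap frequency-profile summaries used for simulator calibration
# ---------------------------------------------------------------------------


def profile_cline_center(freq: np.ndarray, deme_width: float = 1.0) -> float:
    """Center of a per-deme frequency profile: the position where the
    smoothed profile crosses midway between its end frequencies."""
    f = np.convolve(freq, np.ones(5) / 5.0, mode="same")
    p_lo = f[:5].mean()
    p_hi = f[-5:].mean()
    mid = 0.5 * (p_lo + p_hi)
    rising = p_hi >= p_lo
    g = f if rising else -f
    target = mid if rising else -mid
    idx = np.nonzero(g >= target)[0]
    if len(idx) == 0 or idx[0] == 0:
        return 0.5 * deme_width if len(idx) else (len(f) - 0.5) * deme_width
    i = idx[0]
    x0, x1 = (i - 0.5) * deme_width, (i + 0.5) * deme_width
    if g[i] == g[i - 1]:
        return x0
    t = (target - g[i - 1]) / (g[i] - g[i - 1])
    return float(x0 + t * (x1 - x0))


def profile_cline_width(freq: np.ndarray, deme_width: float = 1.0) -> float:
    """Width = |end-frequency difference| / max smoothed gradient."""
    f = np.convolve(freq, np.ones(5) / 5.0, mode="same")
    dp = abs(f[-5:].mean() - f[:5].mean())
    grad = np.abs(np.diff(f)) / deme_width
    gmax = grad.max()
    if gmax <= 0:
        return float("inf")
    return float(dp / gmax)
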