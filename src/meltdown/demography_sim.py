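"""Forward Wright-Fisher simulation of neutral vs selected heterozygosity.

Models the nearly-neutral prediction that a sustained reduction in effective
population size lets weakly deleterious amino-acid variants drift upward,
pushing the ratio of non-synonymous to synonymous heterozygosity (Hn/Hs)
toward parity.  Two classes of fully independent biallelic sites are
simulated ("free recombination"): a neutral class and a selected class whose
per-site selection coefficients are drawn once from a gamma distribution of
fitness effects (negative, mean -0.043, shape 0.23 as estimated for human
amino-acid variants), with additive dominance h = 0.5.

Per generation and site, allele frequency q of the deleterious/derived
allele is updated deterministically by selection with genotype fitnesses
(1, 1+hs, 1+s), then by symmetric recurrent mutation at rate mu, and finally
resampled binomially from 2N gametes.  Heterozygosity per site is 2q(1-q).

A population-size rescaling N -> N/Q, t -> t/Q, mu -> mu*Q, s -> s*Q keeps
the products N*mu and N*s invariant and accelerates the simulation; DFE
draws whose rescaled |s| would exceed 1 are clamped to -1 (fully lethal when
homozygous), which is the strongest selection expressible in the model and
leaves the heterozygosity of such rare strongly-selected sites essentially
unchanged.

The closed-form companion is the neutral decay H_t = H_0 (1 - 1/(2N))^t
applied epoch by epoch along a piecewise-constant trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Population trajectory
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopTrajectory:
    """Piecewise-constant diploid population sizes, ordered past -> present."""

    epochs: tuple[tuple[int, int], ...]  # (N diploid individuals, duration in generations)
    dropped_terminal: bool = False

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("trajectory must contain at least one epoch")
        for i, (N, t) in enumerate(self.epochs):
            if N < 2:
                raise ValueError(f"epoch {i}: N must be >= 2, got {N}")
            if t < 1:
                raise ValueError(f"epoch {i}: duration must be >= 1, got {t}")

    @property
    def total_generations(self) -> int:
        return sum(t for _, t in self.epochs)


def load_trajectory(path: str | Path, drop_terminal: bool = False) -> PopTrajectory:
    """Read a trajectory TSV of (N, generations) rows, past -> present.

    ``drop_terminal`` removes the first and last rows, the usual guard
    against runaway terminal intervals in coalescent-inferred size
    histories.
    """
    rows: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns (N, generations)")
            N, t = int(float(parts[0])), int(float(parts[1]))
            if N < 2 or t < 1:
                raise ValueError(f"{path}:{lineno}: non-positive N or duration")
            rows.append((N, t))
    if not rows:
        raise ValueError(f"{path}: empty trajectory file")
    if drop_terminal:
        rows = rows[1:-1]
        if not rows:
            raise ValueError(f"{path}: no epochs left after dropping terminal rows")
    return PopTrajectory(tuple(rows), dropped_terminal=drop_terminal)


def save_trajectory(traj: PopTrajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# N\tgenerations\n")
        for N, t in traj.epochs:
            fh.write(f"{N}\t{t}\n")


def toy_decline_trajectory() -> PopTrajectory:
    """Three-epoch example: large ancestral population, decline, small isolate.

    Ancestral Ne of 1e4 and a terminal size of 300 individuals bracket the
    mainland-to-island contrast this model targets; the decline epoch is a
    short geometric-ish intermediate.
    """
    return PopTrajectory(((10_000, 20_000), (3_000, 2_000), (300, 2_000)))


# ---------------------------------------------------------------------------
# Parameters and DFE
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters.

    mu: per-site per-generation mutation rate.
    dfe_mean / dfe_shape: gamma distribution of (negative) selection
        coefficients for the selected class.
    h: dominance coefficient of the deleterious allele.
    sites_per_class, replicates: problem size; replicate haplotype sets are
        independent WF universes sharing nothing but parameters.
    burn_in: generations at the first epoch's size before the trajectory
        starts (a floor of 10 N rescaled generations is enforced).
    rescale_q: population-size rescaling factor Q >= 1.
    fixed_s: optional constant selection coefficient overriding the DFE.
    """

    mu: float = 3.8e-8
    dfe_mean: float = -0.043
    dfe_shape: float = 0.23
    h: float = 0.5
    sites_per_class: int = 100
    replicates: int = 460
    burn_in: int = 100_000
    rescale_q: float = 1.0
    fixed_s: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.dfe_mean >= 0:
            raise ValueError("dfe_mean must be negative (deleterious)")
        if self.dfe_shape <= 0:
            raise ValueError("dfe_shape must be positive")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("dominance h must be in [0, 1]")
        if self.rescale_q < 1.0:
            raise ValueError("rescale_q must be >= 1")
        if self.mu * self.rescale_q >= 0.1:
            raise ValueError("mu * Q >= 0.1: rescaling invalid")
        if self.fixed_s is not None and abs(self.fixed_s) * self.rescale_q >= 1.0:
            raise ValueError("|s| * Q >= 1: rescaling invalid")


def sample_dfe(
    n: int, dfe_mean: float = -0.043, dfe_shape: float = 0.23,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw n negative selection coefficients s = -Gamma(shape, |mean|/shape)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if dfe_shape <= 0:
        raise ValueError("shape must be positive")
    if dfe_mean >= 0:
        raise ValueError("mean must be negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return -rng.gamma(dfe_shape, abs(dfe_mean) / dfe_shape, size=n)


# ---------------------------------------------------------------------------
# Forward engine
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """Per-replicate heterozygosity time series for both site classes.

    ``times`` are unscaled generation offsets from the start of the
    trajectory (burn-in excluded); arrays are (n_times, replicates), each
    entry the mean 2q(1-q) over that replicate's sites.
    """

    times: np.ndarray
    h_neutral: np.ndarray
    h_selected: np.ndarray
    selection_coeffs: np.ndarray = field(repr=False, default=None)


def _evolve(
    q: np.ndarray, s: np.ndarray | None, h: float, mu: float, twoN: int,
    n_gens: int, rng: np.random.Generator,
    sample_gens: Sequence[int] = (), out: list | None = None,
) -> np.ndarray:
    """Advance allele frequencies n_gens generations; record 2q(1-q) at
    sampled generation indices (0-based, generation counted after update)."""
    sample_set = set(sample_gens)
    for g in range(n_gens):
        if s is not None:
            wbar = 1.0 + 2.0 * q * (1.0 - q) * h * s + q * q * s
            q = (q * q * (1.0 + s) + q * (1.0 - q) * (1.0 + h * s)) / wbar
        q = q * (1.0 - mu) + (1.0 - q) * mu
        q = rng.binomial(twoN, q) / twoN
        if g in sample_set and out is not None:
            out.append(2.0 * q * (1.0 - q))
    return q


def simulate_forward(
    trajectory: PopTrajectory,
    params: SimParams,
    sample_times: Sequence[int] | None = None,
) -> SimResult:
    """Simulate both site classes through a population-size trajectory.

    ``sample_times`` are unscaled generation offsets from the start of the
    trajectory at which heterozygosity is recorded; default is the end of
    each epoch.  Fixed seed implies identical output.
    """
    Q = params.rescale_q
    mu = params.mu * Q
    epochs = [(max(2, round(N / Q)), max(1, round(t / Q))) for N, t in trajectory.epochs]
    n_sites = params.sites_per_class * params.replicates
    rng = np.random.default_rng(params.seed)

    if params.fixed_s is not None:
        s_sel = np.full(n_sites, params.fixed_s * Q)
    else:
        s_sel = sample_dfe(n_sites, params.dfe_mean, params.dfe_shape, rng) * Q
        s_sel = np.maximum(s_sel, -1.0)  # lethal floor after rescaling

    if sample_times is None:
        acc, sample_times = 0, []
        for _, t in trajectory.epochs:
            acc += t
            sample_times.append(acc)
    sample_times = sorted(set(sample_times))
    # map unscaled offsets to rescaled generation indices
    total_rescaled = sum(t for _, t in epochs)
    time_to_scaled = {
        t: min(total_rescaled - 1, max(0, round(t / Q) - 1)) for t in sample_times
    }
    scaled = sorted(set(time_to_scaled.values()))

    N0 = epochs[0][0]
    burn = max(round(params.burn_in / Q), 10 * N0)
    q_neu = np.zeros(n_sites)
    q_sel = np.zeros(n_sites)
    q_neu = _evolve(q_neu, None, params.h, mu, 2 * N0, burn, rng)
    q_sel = _evolve(q_sel, s_sel, params.h, mu, 2 * N0, burn, rng)

    h_neu: list[np.ndarray] = []
    h_sel: list[np.ndarray] = []
    g0 = 0
    for N, t in epochs:
        local = [g - g0 for g in scaled if g0 <= g < g0 + t]
        q_neu = _evolve(q_neu, None, params.h, mu, 2 * N, t, rng, local, h_neu)
        q_sel = _evolve(q_sel, s_sel, params.h, mu, 2 * N, t, rng, local, h_sel)
        g0 += t

    row_of_scaled = {g: i for i, g in enumerate(scaled)}

    def stack(rows):
        arr = np.stack(rows) if rows else np.empty((0, n_sites))
        per_rep = arr.reshape(-1, params.replicates, params.sites_per_class).mean(axis=2)
        # expand rows so each requested unscaled time has its own row
        return per_rep[[row_of_scaled[time_to_scaled[t]] for t in sample_times]]

    return SimResult(
        times=np.asarray(sample_times),
        h_neutral=stack(h_neu),
        h_selected=stack(h_sel),
        selection_coeffs=s_sel / Q,
    )


def equilibrium_hn_hs(
    N: int,
    params: SimParams,
    sample_window: int = 50_000,
    sample_every: int = 500,
) -> SimResult:
    """Equilibrium run at constant size N, time-averaging H over a window.

    Burn-in precedes a single epoch of ``sample_window`` (unscaled)
    generations sampled every ``sample_every`` generations; averaging the
    correlated samples sharpens the equilibrium estimate without biasing it.
    """
    traj = PopTrajectory(((N, sample_window),))
    times = list(range(sample_every, sample_window + 1, sample_every))
    return simulate_forward(traj, params, sample_times=times)


# ---------------------------------------------------------------------------
# Closed forms and summaries
# ---------------------------------------------------------------------------


def expected_neutral_decay(H0: float, trajectory: PopTrajectory) -> list[float]:
    """Expected neutral heterozygosity at the end of each epoch.

    Pure drift: H is multiplied by (1 - 1/(2N))^t per epoch, sequentially.
    """
    if not 0.0 <= H0 <= 1.0:
        raise ValueError("H0 must be in [0, 1]")
    out, H = [], H0
    for N, t in trajectory.epochs:
        H = H * (1.0 - 1.0 / (2.0 * N)) ** t
        out.append(H)
    return out


def expected_neutral_equilibrium_het(N: int, mu: float) -> float:
    """Diffusion equilibrium mean heterozygosity, symmetric biallelic mutation.

    The stationary frequency distribution is Beta(4N mu, 4N mu), giving
    E[2p(1-p)] = 4N mu / (1 + 8N mu); this reduces to 4N mu for small theta
    and is exact in the diffusion limit (verified against the full discrete
    Markov chain in the test suite).
    """
    theta = 4.0 * N * mu
    return theta / (1.0 + 2.0 * theta)


def mutation_selection_het(mu: float, h: float, s: float) -> float:
    """Deterministic mutation-selection balance heterozygosity 2 mu / (h |s|).

    Valid for 2Nh|s| >> 1 and h|s| >> mu (partially recessive to additive).
    """
    return 2.0 * mu / (h * abs(s))


@dataclass(frozen=True)
class ReplicateSummary:
    h_neutral: float
    h_selected: float
    ratio: float | None
    ci_low: float | None
    ci_high: float | None


def summarize_replicates(
    result: SimResult,
    n_boot: int = 2000,
    seed: int = 0,
) -> ReplicateSummary:
    """Class means over replicates (and sample times), ratio of means, and a
    percentile bootstrap CI for the ratio over replicates."""
    h_neu = np.atleast_2d(result.h_neutral).mean(axis=0)
    h_sel = np.atleast_2d(result.h_selected).mean(axis=0)
    if len(h_neu) < 2:
        raise ValueError("need at least two replicates")
    mean_neu = float(h_neu.mean())
    mean_sel = float(h_sel.mean())
    if mean_neu <= 0:
        logger.warning("neutral heterozygosity is zero; ratio undefined")
        return ReplicateSummary(mean_neu, mean_sel, None, None, None)
    ratio = mean_sel / mean_neu
    rng = np.random.default_rng(seed)
    reps = len(h_neu)
    idx = rng.integers(0, reps, size=(n_boot, reps))
    boot_neu = h_neu[idx].mean(axis=1)
    boot_sel = h_sel[idx].mean(axis=1)
    ok = boot_neu > 0
    boot_ratio = boot_sel[ok] / boot_neu[ok]
    lo, hi = np.percentile(boot_ratio, [2.5, 97.5])
    return ReplicateSummary(mean_neu, mean_sel, ratio, float(lo), float(hi))
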