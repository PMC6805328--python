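"""Synthetic heterogeneous expression data with known ground truth.

Data are drawn from the additive generative models

    unsupervised:  X = G eta             + F phi + eps
    supervised:    X = Y gamma + G eta   + F phi + eps,    eps ~ N(0, sigma^2)

with a sparse set of planted signal genes carrying the interest-factor
effect (the rows of gamma — or of eta in unsupervised problems — are
nonzero only at those genes), K standardized latent factor columns in F
with dense gene loadings phi, and i.i.d. Gaussian noise.  A mixing knob
lets F correlate with the interest design, creating the confounding that
adjustment is meant to remove.  Effect sizes can be pinned as variance
shares of the total signal so scenarios stay comparable across n and p.
Every stored component reconstructs X exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .adjust import ExpressionMatrix, FactorDesign

__all__ = ["SimConfig", "SimTruth", "simulate_dataset", "spike_in_scenario"]


@dataclass
class SimConfig:
    """Scenario description for :func:`simulate_dataset`.

    Scales are coefficient standard deviations; when ``variance_shares`` is
    given (per-component shares for outcome, group, latent, noise summing
    to 1) the drawn components are rescaled so their realised sums of
    squares match those shares exactly.
    """

    n_samples: int = 60
    n_genes: int = 2000
    n_groups: int = 4
    group_effect: float = 1.0
    n_classes: int | None = None  # None => unsupervised (no outcome)
    outcome_effect: float = 1.0
    n_signal_genes: int = 16
    signal_gene_policy: str = "first"  # "first" | "random"
    signal_pattern: str = "gaussian"  # "gaussian" | "ladder"
    k_latent: int = 0
    latent_scale: float = 1.0
    noise_sd: float = 1.0
    factor_design_correlation: float = 0.0  # rho mixing F with the interest design
    variance_shares: tuple[float, float, float, float] | None = None
    group_sizes: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_genes < 1 or self.n_groups < 1:
            raise ValueError("counts must be positive (n_samples >= 2)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.n_signal_genes <= self.n_genes:
            raise ValueError("n_signal_genes must be in [0, n_genes]")
        if not -1.0 <= self.factor_design_correlation <= 1.0:
            raise ValueError("factor_design_correlation must be in [-1, 1]")
        if self.k_latent > 0 and self.latent_scale == 0:
            warnings.warn("k_latent > 0 with zero latent_scale: factors are inert",
                          stacklevel=2)
        if self.group_sizes is not None:
            if len(self.group_sizes) != self.n_groups:
                raise ValueError("group_sizes length must equal n_groups")
            if sum(self.group_sizes) != self.n_samples:
                raise ValueError("group_sizes must sum to n_samples")

    @property
    def supervised(self) -> bool:
        return self.n_classes is not None


@dataclass
class SimTruth:
    """Every generative component, enabling exact reconstruction of X."""

    G: np.ndarray
    Y: np.ndarray | None
    F_true: np.ndarray
    eta: np.ndarray
    gamma: np.ndarray | None
    phi: np.ndarray
    epsilon: np.ndarray
    signal_gene_indices: np.ndarray
    metadata: dict = field(default_factory=dict)

    def reconstruct(self) -> np.ndarray:
        X = self.G @ self.eta + self.F_true @ self.phi + self.epsilon
        if self.Y is not None and self.gamma is not None:
            X = X + self.Y @ self.gamma
        return X

    def component_variance_shares(self) -> dict[str, float]:
        parts = {
            "outcome": self.Y @ self.gamma if self.Y is not None else None,
            "group": self.G @ self.eta,
            "latent": self.F_true @ self.phi,
            "noise": self.epsilon,
        }
        ss = {k: float(np.sum(v**2)) for k, v in parts.items() if v is not None}
        total = sum(ss.values())
        return {k: v / total if total else 0.0 for k, v in ss.items()}


def _balanced_sizes(n: int, g: int) -> list[int]:
    base, extra = divmod(n, g)
    return [base + (1 if i < extra else 0) for i in range(g)]


def _standardize_columns(F: np.ndarray) -> np.ndarray:
    F = F - F.mean(axis=0, keepdims=True)
    sd = F.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return F / sd


def simulate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, FactorDesign, SimTruth]:
    """Draw one dataset from the generative model; reproducible from seed."""
    rng = np.random.default_rng(config.seed)
    n, p, g = config.n_samples, config.n_genes, config.n_groups
    sizes = list(config.group_sizes) if config.group_sizes else _balanced_sizes(n, g)
    group_of = np.repeat(np.arange(g), sizes)
    G = np.zeros((n, g))
    G[np.arange(n), group_of] = 1.0

    if config.signal_gene_policy == "first":
        signal = np.arange(config.n_signal_genes)
    elif config.signal_gene_policy == "random":
        signal = np.sort(rng.choice(p, size=config.n_signal_genes, replace=False))
    else:
        raise ValueError(f"unknown signal_gene_policy {config.signal_gene_policy!r}")

    def _interest_effects(rows: int, cols: np.ndarray) -> np.ndarray:
        """Effect rows for the planted signal genes.

        ``gaussian`` draws i.i.d. N(0, scale^2) effects; ``ladder`` gives
        every signal gene the same per-gene effect size — a permuted,
        centered concentration series across the levels, the way spike-in
        transcripts cycle through a fixed ladder of concentrations — so no
        planted gene is weak by luck of the draw.
        """
        scale = config.group_effect if not config.supervised else config.outcome_effect
        if config.signal_pattern == "gaussian":
            return rng.normal(0.0, scale, (rows, len(cols)))
        if config.signal_pattern != "ladder":
            raise ValueError(f"unknown signal_pattern {config.signal_pattern!r}")
        ladder = np.linspace(-1.0, 1.0, rows)
        ladder = ladder / ladder.std() if rows > 1 else ladder
        out = np.empty((rows, len(cols)))
        for i in range(len(cols)):
            out[:, i] = scale * ladder[rng.permutation(rows)]
        return out

    Y = gamma = None
    if config.supervised:
        q = int(config.n_classes)  # type: ignore[arg-type]
        if q < 2:
            raise ValueError("n_classes must be >= 2 in supervised scenarios")
        class_of = np.arange(n) % q  # interleaved so classes cut across groups
        class_of = rng.permutation(class_of)
        Y = np.zeros((n, q))
        Y[np.arange(n), class_of] = 1.0
        gamma = np.zeros((q, p))
        gamma[:, signal] = _interest_effects(q, signal)
        # the nuisance grouping (batch) affects all genes broadly
        eta = rng.normal(0.0, config.group_effect, (g, p))
        interest_codes = Y
    else:
        # the grouping is of interest: planted differential genes live in eta
        eta = np.zeros((g, p))
        eta[:, signal] = _interest_effects(g, signal)
        interest_codes = G

    K = config.k_latent
    if K > 0:
        F = rng.normal(size=(n, K))
        rho = config.factor_design_correlation
        if rho != 0.0:
            # blend each factor with a random contrast over the interest design
            contrast = interest_codes @ rng.normal(size=(interest_codes.shape[1], K))
            F = np.sqrt(1 - rho**2) * _standardize_columns(F) + rho * _standardize_columns(contrast)
        F = _standardize_columns(F)
        phi = rng.normal(0.0, config.latent_scale, (K, p))
    else:
        F = np.empty((n, 0))
        phi = np.empty((0, p))

    epsilon = rng.normal(0.0, config.noise_sd, (n, p)) if config.noise_sd > 0 else np.zeros((n, p))

    if config.variance_shares is not None:
        shares = np.asarray(config.variance_shares, dtype=float)
        if shares.shape != (4,) or np.any(shares < 0) or not np.isclose(shares.sum(), 1.0):
            raise ValueError("variance_shares must be 4 non-negative values summing to 1")
        comps = {
            "outcome": (Y @ gamma) if Y is not None else None,
            "group": G @ eta,
            "latent": F @ phi,
            "noise": epsilon,
        }
        total = sum(float(np.sum(c**2)) for c in comps.values() if c is not None)
        for i, (name, holder) in enumerate(
            (("outcome", "gamma"), ("group", "eta"), ("latent", "phi"), ("noise", None))
        ):
            comp = comps[name]
            if comp is None:
                continue
            ss = float(np.sum(comp**2))
            if ss == 0:
                if shares[i] > 0:
                    warnings.warn(
                        f"variance share requested for inert component {name!r}",
                        stacklevel=2,
                    )
                continue
            scale = np.sqrt(shares[i] * total / ss)
            if name == "outcome":
                gamma = gamma * scale  # type: ignore[operator]
            elif name == "group":
                eta = eta * scale
            elif name == "latent":
                phi = phi * scale
            else:
                epsilon = epsilon * scale

    X = G @ eta + F @ phi + epsilon
    if Y is not None:
        X = X + Y @ gamma

    sample_ids = [f"S{i+1:03d}" for i in range(n)]
    gene_ids = [f"gene_{j+1:05d}" for j in range(p)]
    group_labels = [f"grp{j+1:02d}" for j in range(g)]
    expr = ExpressionMatrix(values=X, sample_ids=sample_ids, gene_ids=gene_ids)
    design = FactorDesign(
        G=G,
        group_labels=group_labels,
        Y=Y,
        mode="supervised" if config.supervised else "unsupervised",
    )
    truth = SimTruth(
        G=G, Y=Y, F_true=F, eta=eta, gamma=gamma, phi=phi, epsilon=epsilon,
        signal_gene_indices=np.asarray(signal),
        metadata={"config": config, "group_sizes": sizes},
    )
    return expr, design, truth


def spike_in_scenario(
    seed: int = 0,
    n_genes: int = 2000,
    group_effect: float = 2.0,
    latent_scale: float = 3.0,
    k_latent: int = 6,
    confounding: float = 0.5,
    noise_sd: float = 1.0,
) -> tuple[ExpressionMatrix, FactorDesign, SimTruth]:
    """An unsupervised fixture shaped like a classic spike-in benchmark.

    14 replicate array groups — twelve triplicate groups and two groups of
    twelve replicates, with one replicate dropped from the last triplicate
    group so the total is 59 arrays — and 16 planted genes (at random
    positions) that alone differentiate the groups, each cycling through a
    permuted concentration ladder, on top of several strong latent
    confounding factors correlated with the grouping.  ``group_effect=2``
    is a high-signal regime (per-gene between-group standard deviation
    twice the noise); lower it toward ~0.75 for a contested, moderate-SNR
    regime.  The replicate drop is recorded in the truth metadata.
    """
    sizes = [3] * 12 + [12, 12]
    sizes[11] = 2  # 60 -> 59 arrays: one replicate removed from the last triplicate
    config = SimConfig(
        n_samples=59,
        n_genes=n_genes,
        n_groups=14,
        group_effect=group_effect,
        n_classes=None,
        n_signal_genes=16,
        signal_gene_policy="random",
        signal_pattern="ladder",
        k_latent=k_latent,
        latent_scale=latent_scale,
        noise_sd=noise_sd,
        factor_design_correlation=confounding,
        group_sizes=tuple(sizes),
        seed=seed,
    )
    expr, design, truth = simulate_dataset(config)
    truth.metadata["dropped_replicate"] = "one replicate removed from group 12"
    return expr, design, truth
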