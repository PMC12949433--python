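"""Synthetic data generator for the simulation study.

Proteins are multivariate normal, X ~ N_p(0, Σ), where Σ couples a
hub cluster to an autoregressive chain:

* Σ_jj = 1;
* Σ_jk = 0.9 for j ≠ k both in the cluster {1, 2, 3, 4};
* Σ_jk = 0.9^{|j−k|} for every other pair (the AR(0.9) backbone, which also
  supplies the cluster↔chain cross-correlations).

Under this structure the proteins with the largest true degree centrality are
{5, 4, 1, 3, 2}: the cluster plus the chain node it abuts, which is the "hub
cluster bridging an AR chain" design the study is built around.  Positive
definiteness is asserted at construction.

Confounders are Z1 ~ U(0, 1), Z2 ~ Bernoulli(0.25), Z3 ~ Bernoulli(0.65) and
the outcome is linear-Gaussian,

    Y = μ + Zζ + Xη + ε,   ε ~ N(0, σ²),

with μ = 0.5, ζ = (2.5, 2.5, 2.5), σ = 1 and two signal scenarios for η:

* strong: η = (3.5·1₅, 0₅, −1.5·1₅, 0_{p−15})  — support {1..5, 11..15};
* weak:   η = (1, −0.8, 0.6, 0, 0, −1.5, −0.5, 1.2, 0_{p−8}) — support
  {1, 2, 3, 6, 7, 8}.

Named sample-size/dimension settings: I = (50, 60), II = (100, 60),
III = (100, 300).  Train and test sets are independent draws from the same
process, reproducible from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import ExpressionMatrix

SETTINGS = {"I": (50, 60), "II": (100, 60), "III": (100, 300)}

STRONG_SUPPORT = (0, 1, 2, 3, 4, 10, 11, 12, 13, 14)  # zero-based
WEAK_SUPPORT = (0, 1, 2, 5, 6, 7)

CONFOUNDER_NAMES = ["Z1", "Z2", "Z3"]


@dataclass(frozen=True)
class SimScenario:
    """Full specification of one data-generating configuration."""

    n: int
    p: int
    signal: str
    seed: int
    sigma: float = 1.0
    mu: float = 0.5
    zeta: tuple[float, float, float] = (2.5, 2.5, 2.5)
    test_n: int = 1000

    def __post_init__(self):
        if self.signal not in ("strong", "weak"):
            raise ValueError(f"signal must be 'strong' or 'weak', got {self.signal}")
        min_p = 15 if self.signal == "strong" else 8
        if self.p < min_p:
            raise ValueError(
                f"{self.signal} signal needs p >= {min_p}, got {self.p}"
            )
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @classmethod
    def from_setting(cls, setting: str, signal: str, seed: int, **kw) -> "SimScenario":
        if setting not in SETTINGS:
            raise ValueError(f"unknown setting {setting!r}; use I, II or III")
        n, p = SETTINGS[setting]
        return cls(n=n, p=p, signal=signal, seed=seed, **kw)

    def with_seed(self, seed: int) -> "SimScenario":
        return replace(self, seed=seed)


@dataclass
class SimDataset:
    x_train: ExpressionMatrix
    z_train: np.ndarray
    y_train: np.ndarray
    x_test: ExpressionMatrix
    z_test: np.ndarray
    y_test: np.ndarray
    mean_test: np.ndarray  # noiseless E[Y | X, Z] on the test set
    eta_true: np.ndarray
    true_support: list[int]  # protein indices (zero-based) with nonzero eta
    scenario: SimScenario = field(repr=False, default=None)

    @property
    def candidate_truth(self) -> np.ndarray:
        """Truth mask over the p + c candidates (confounders first).

        Confounders count as true variables since ζ = (2.5, 2.5, 2.5) is
        nonzero throughout.
        """
        c = self.z_train.shape[1]
        p = self.x_train.n_features
        mask = np.zeros(p + c, dtype=bool)
        mask[:c] = True
        mask[[c + j for j in self.true_support]] = True
        return mask


def make_sigma(p: int) -> np.ndarray:
    """Protein covariance: AR(0.9) backbone with the {1..4} cluster at 0.9."""
    if p < 5:
        raise ValueError(f"need p >= 5, got {p}")
    idx = np.arange(p)
    sigma = 0.9 ** np.abs(idx[:, None] - idx[None, :])
    sigma[:4, :4] = 0.9
    np.fill_diagonal(sigma, 1.0)
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - construction bug
        raise RuntimeError("simulated covariance is not positive definite") from exc
    return sigma


def make_eta(signal: str, p: int) -> np.ndarray:
    eta = np.zeros(p)
    if signal == "strong":
        eta[0:5] = 3.5
        eta[10:15] = -1.5
    elif signal == "weak":
        eta[0:8] = [1.0, -0.8, 0.6, 0.0, 0.0, -1.5, -0.5, 1.2]
    else:
        raise ValueError(f"unknown signal scenario {signal!r}")
    return eta


def _draw(rng: np.random.Generator, n: int, chol: np.ndarray, scn: SimScenario,
          eta: np.ndarray):
    p = chol.shape[0]
    x = rng.standard_normal((n, p)) @ chol.T
    z = np.column_stack(
        [
            rng.uniform(0.0, 1.0, size=n),
            rng.binomial(1, 0.25, size=n).astype(float),
            rng.binomial(1, 0.65, size=n).astype(float),
        ]
    )
    eps = rng.normal(0.0, scn.sigma, size=n)
    mean = scn.mu + z @ np.asarray(scn.zeta) + x @ eta
    return x, z, mean + eps, mean


def simulate(scn: SimScenario) -> SimDataset:
    """Draw independent train and test sets, fully reproducible from the seed."""
    sigma = make_sigma(scn.p)
    chol = np.linalg.cholesky(sigma)
    eta = make_eta(scn.signal, scn.p)

    ss = np.random.SeedSequence(scn.seed)
    train_ss, test_ss = ss.spawn(2)
    x_tr, z_tr, y_tr, _ = _draw(np.random.default_rng(train_ss), scn.n, chol, scn, eta)
    x_te, z_te, y_te, mean_te = _draw(
        np.random.default_rng(test_ss), scn.test_n, chol, scn, eta
    )

    support = sorted(np.flatnonzero(eta != 0).tolist())
    expected = list(STRONG_SUPPORT if scn.signal == "strong" else WEAK_SUPPORT)
    assert support == expected, "generated support does not match the scenario"

    names = [f"X{j + 1}" for j in range(scn.p)]
    return SimDataset(
        x_train=ExpressionMatrix(
            x_tr, names, [f"train{i + 1}" for i in range(scn.n)]
        ),
        z_train=z_tr,
        y_train=y_tr,
        x_test=ExpressionMatrix(
            x_te, names, [f"test{i + 1}" for i in range(scn.test_n)]
        ),
        z_test=z_te,
        y_test=y_te,
        mean_test=mean_te,
        eta_true=eta,
        true_support=support,
        scenario=scn,
    )
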