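"""Minimal (mu/mu_w, lambda) covariance-matrix-adaptation evolution strategy.

Standard CMA-ES with rank-one and rank-mu covariance updates and
cumulative step-size adaptation, restricted to box-bounded problems by
projection repair (candidates are clipped into the bounds before
evaluation and before the distribution update, so out-of-bound points are
never evaluated).  Only the pieces needed for seeding the exploration
loop are implemented: ask/tell with default Hansen-style constants.
"""

from __future__ import annotations

import numpy as np


class CMAES:
    def __init__(self, x0, sigma0: float, bounds=(0.0, 1.0), popsize: int | None = None,
                 rng: np.random.Generator | None = None):
        self.m = np.asarray(x0, dtype=float).copy()
        self.n = self.m.size
        self.sigma = float(sigma0)
        self.lo, self.hi = bounds
        self.rng = rng or np.random.default_rng()

        n = self.n
        self.lam = popsize or 4 + int(3 * np.log(n))
        self.mu = self.lam // 2
        w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.w = w / w.sum()
        self.mueff = 1.0 / np.sum(self.w**2)

        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(
            1 - self.c1,
            2 * (self.mueff - 2 + 1 / self.mueff) / ((n + 2) ** 2 + self.mueff),
        )
        self.damps = 1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (n + 1)) - 1) + self.cs
        self.chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self._decompose()
        self.generation = 0

    def _decompose(self) -> None:
        self.C = (self.C + self.C.T) / 2
        d, b = np.linalg.eigh(self.C)
        d = np.maximum(d, 1e-20)
        self.B = b
        self.D = np.sqrt(d)
        self.inv_sqrt_c = b @ np.diag(1.0 / self.D) @ b.T

    def ask(self) -> np.ndarray:
        """Sample lam candidates, clipped into the box bounds."""
        z = self.rng.standard_normal((self.lam, self.n))
        y = z @ (self.B * self.D).T
        x = self.m + self.sigma * y
        return np.clip(x, self.lo, self.hi)

    def tell(self, xs: np.ndarray, fitness) -> None:
        """Rank by fitness (minimization) and update the distribution."""
        order = np.argsort(np.asarray(fitness))
        xs = np.asarray(xs)[order[: self.mu]]
        y = (xs - self.m) / self.sigma
        y_w = self.w @ y
        self.m = self.m + self.sigma * y_w
        self.m = np.clip(self.m, self.lo, self.hi)

        self.ps = (1 - self.cs) * self.ps + np.sqrt(
            self.cs * (2 - self.cs) * self.mueff
        ) * (self.inv_sqrt_c @ y_w)
        hsig = (
            np.linalg.norm(self.ps)
            / np.sqrt(1 - (1 - self.cs) ** (2 * (self.generation + 1)))
            / self.chi_n
            < 1.4 + 2 / (self.n + 1)
        )
        self.pc = (1 - self.cc) * self.pc + hsig * np.sqrt(
            self.cc * (2 - self.cc) * self.mueff
        ) * y_w

        rank_mu = sum(w * np.outer(yi, yi) for w, yi in zip(self.w, y))
        self.C = (
            (1 - self.c1 - self.cmu) * self.C
            + self.c1 * (np.outer(self.pc, self.pc)
                         + (not hsig) * self.cc * (2 - self.cc) * self.C)
            + self.cmu * rank_mu
        )
        self.sigma *= np.exp(
            (self.cs / self.damps) * (np.linalg.norm(self.ps) / self.chi_n - 1)
        )
        self.sigma = float(min(self.sigma, 1.0))
        self.generation += 1
        self._decompose()
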