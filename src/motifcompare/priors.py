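"""Prior distributions for rate-law parameters and the noise variance.

All kinetic parameters (production and degradation rates, activation
thresholds, delays) share a log-normal prior with mean 0 and standard
deviation 1 in log space -- a weakly informative choice centred on rate 1
in the dimensionless units of the study, identical across models so the
evidence comparison is fair.  The observation-noise variance sigma^2
carries an inverse-gamma prior with shape 0.5 and scale 0.05: heavy
tailed, mean undefined, mode at 0.05/1.5 = 0.1/3.

Sampling happens on the log scale, where the log-normal becomes a
standard normal and the inverse-gamma acquires a change-of-variables
Jacobian; both log densities below are densities *of the log-scale
variable*, so evidence estimates computed with them are
parameterisation-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = ["PriorSet"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorSet:
    """Independent priors: log-normal rates, inverse-gamma noise variance."""

    rate_log_mean: float = 0.0
    rate_log_sd: float = 1.0
    noise_shape: float = 0.5
    noise_scale: float = 0.05

    def log_prior_rates(self, x_log: np.ndarray) -> float:
        """Log density of the kinetic parameters, as a function of log theta."""
        z = (np.asarray(x_log) - self.rate_log_mean) / self.rate_log_sd
        n = z.size
        return float(-0.5 * np.dot(z, z) - n * (np.log(self.rate_log_sd) + 0.5 * _LOG_2PI))

    def log_prior_noise(self, u: float) -> float:
        """Log density of u = log sigma^2 (inverse-gamma plus Jacobian)."""
        a, b = self.noise_shape, self.noise_scale
        return float(a * np.log(b) - gammaln(a) - a * u - b * np.exp(-u))

    def log_prior(self, x_log: np.ndarray) -> float:
        """Joint log prior of [log rates..., log sigma^2]."""
        x_log = np.asarray(x_log, dtype=float)
        return self.log_prior_rates(x_log[:-1]) + self.log_prior_noise(x_log[-1])

    @property
    def noise_mode(self) -> float:
        """Prior mode of sigma^2 (= scale / (shape + 1))."""
        return self.noise_scale / (self.noise_shape + 1.0)

    def sample(self, n_rates: int, rng: np.random.Generator) -> np.ndarray:
        """Draw [log rates..., log sigma^2] from the prior (used in tests)."""
        x = rng.normal(self.rate_log_mean, self.rate_log_sd, size=n_rates)
        sigma2 = 1.0 / rng.gamma(self.noise_shape, 1.0 / self.noise_scale)
        return np.concatenate([x, [np.log(sigma2)]])
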