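"""Two-domain synthetic expression generator with known ground truth.

Three gene roles:

* ``invariant_informative`` — class-conditionally Gaussian with a class
  mean shift of ``effect_size`` s.d. units (alternating sign), identical
  law in both domains given the label.  These satisfy the
  domain-adaptation condition and carry the signal.
* ``invariant_null`` — pure noise, identical in both domains.
* ``shifted`` — nuisance genes whose distribution differs across domains:
  the target mean is offset by ``shift_size`` s.d. units (optionally with
  variance inflation).  By default they additionally carry a class effect
  of ``shifted_source_effect`` s.d. units in the *source only*: genes that
  look predictive in cell lines but whose class relationship breaks in the
  target, the mechanism behind negative transfer.  Set
  ``shifted_source_effect=0`` for purely label-independent shifted genes.

Responder proportions are configurable per domain, so the source-to-target
odds ratio r is controllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets_io import DataError, DomainDataset, ExpressionMatrix, ResponseLabels


@dataclass
class SyntheticConfig:
    n_source: int = 200
    n_target: int = 200
    pi_source: float = 0.5
    pi_target: float = 0.5
    n_invariant_informative: int = 50
    n_invariant_null: int = 100
    n_shifted: int = 500
    effect_size: float = 1.0
    shift_size: float = 3.0
    shifted_source_effect: float | None = None  # None -> effect_size
    shift_var_inflation: float = 1.0  # multiplies the target s.d. of shifted genes
    noise_sd: float = 1.0
    heavy_tails: bool = False  # t(3) noise instead of Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.n_invariant_informative + self.n_invariant_null + self.n_shifted
        if total < 1 or min(
            self.n_invariant_informative, self.n_invariant_null, self.n_shifted
        ) < 0:
            raise DataError("gene counts must be non-negative with total >= 1")
        for pi in (self.pi_source, self.pi_target):
            if not 0.0 < pi < 1.0:
                raise DataError("responder proportions must lie in (0,1)")
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        if min(self.n_source, self.n_target) < 1:
            raise DataError("sample sizes must be >= 1")


@dataclass
class GroundTruth:
    roles: dict[str, str]  # gene_id -> role
    true_beta: dict[str, float]  # class effect per gene (source domain)
    r_true: float

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g, r in self.roles.items() if r == role]


def _gene_ids(config: SyntheticConfig) -> tuple[list[str], list[str], list[str]]:
    inf = [f"g_inf_{i:04d}" for i in range(config.n_invariant_informative)]
    null = [f"g_null_{i:04d}" for i in range(config.n_invariant_null)]
    shift = [f"g_shift_{i:04d}" for i in range(config.n_shifted)]
    return inf, null, shift


def generate_domain_pair(
    config: SyntheticConfig,
) -> tuple[DomainDataset, DomainDataset, GroundTruth]:
    """Draw a (source, target, ground-truth) triple; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    inf, null, shift = _gene_ids(config)
    genes = inf + null + shift
    sse = (
        config.effect_size
        if config.shifted_source_effect is None
        else config.shifted_source_effect
    )

    # alternating class-effect signs avoid a degenerate all-positive logit
    signs_inf = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(inf))])
    signs_shift = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(shift))])

    def noise(shape: tuple[int, ...]) -> np.ndarray:
        if config.heavy_tails:
            # t(3) scaled to unit variance, then to noise_sd
            return rng.standard_t(3, size=shape) / np.sqrt(3.0) * config.noise_sd
        return rng.normal(0.0, config.noise_sd, size=shape)

    def draw_domain(n: int, pi: float, domain: str, prefix: str) -> DomainDataset:
        y = (rng.random(n) < pi).astype(int)
        values = np.empty((len(genes), n))
        row = 0
        es = config.effect_size * config.noise_sd
        for j in range(len(inf)):
            values[row] = es * signs_inf[j] * y + noise((n,))
            row += 1
        for _ in range(len(null)):
            values[row] = noise((n,))
            row += 1
        sse_sd = sse * config.noise_sd
        shift_off = config.shift_size * config.noise_sd
        for j in range(len(shift)):
            if domain == "source":
                values[row] = sse_sd * signs_shift[j] * y + noise((n,))
            else:
                values[row] = shift_off + config.shift_var_inflation * noise((n,))
            row += 1
        sample_ids = [f"{prefix}{i:04d}" for i in range(n)]
        expr = ExpressionMatrix(list(genes), sample_ids, values)
        labels = ResponseLabels(sample_ids, y)
        return DomainDataset(expr, labels, domain, drug_name="synthetic")

    source = draw_domain(config.n_source, config.pi_source, "source", "S")
    target = draw_domain(config.n_target, config.pi_target, "target", "T")

    roles = {g: "invariant_informative" for g in inf}
    roles.update({g: "invariant_null" for g in null})
    roles.update({g: "shifted" for g in shift})
    beta = {g: config.effect_size * s for g, s in zip(inf, signs_inf)}
    beta.update({g: 0.0 for g in null})
    beta.update({g: sse * s for g, s in zip(shift, signs_shift)})
    r_true = (config.pi_source / (1 - config.pi_source)) / (
        config.pi_target / (1 - config.pi_target)
    )
    return source, target, GroundTruth(roles=roles, true_beta=beta, r_true=r_true)
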