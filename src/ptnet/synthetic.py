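"""Synthetic trait matrices with planted correlation modules.

The generator emulates the sampling design the analysis assumes:
several water bodies (groups), ~30 individuals each, 18 traits whose
correlation matrix has a block (module) structure — correlation
``rho_in`` within planted modules and ``rho_out`` between them. A
group-level environmental gradient links a phosphorus-like variable
(TP) positively, and an oxygen-like variable (DO) negatively, to that
group's ``rho_in``, so that denser, shorter-path networks arise at the
nutrient-rich end of the gradient — the tight-vs-loose contrast the
analysis is designed to detect.

Individuals are drawn from a multivariate normal with the block
correlation matrix and then shifted so each trait hits its target
coefficient of variation: trait j is ``z_j + 1/cv_j`` (unit variance,
mean ``1/cv_j``), an affine map that leaves correlations untouched.
All randomness flows from the explicit seed in the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .trait_data import DEFAULT_TRAITS, EnvTable, TraitMatrix

#: Default per-trait target CVs: most variable first, spanning the
#: spread typical of field-collected morphometric and biomass traits.
_CV_ORDER = (
    "SB", "DLW", "RLA", "DPW", "LN", "DSW", "NN", "LT", "SLR",
    "RSL", "NL", "H", "LA", "LMF", "SMF", "LL", "ND", "LW",
)


def default_cv_spec() -> dict[str, float]:
    """Target CVs from 0.75 down to 0.10 along the variability ranking."""
    levels = np.linspace(0.75, 0.10, len(_CV_ORDER))
    return {t: float(c) for t, c in zip(_CV_ORDER, levels)}


@dataclass
class EnvModel:
    """Linear link from the group gradient to environment and rho_in.

    The gradient u runs 0..1 over groups. TP rises along u over
    ``tp_range`` (mg/L), DO falls over ``do_range`` (mg/L), and the
    within-module correlation rises linearly from ``rho_in_range[0]``
    to ``rho_in_range[1]``. ``env_noise_sd`` adds Gaussian jitter
    (fraction of each variable's span) to the environmental readings.
    """

    tp_range: tuple[float, float] = (0.014, 0.055)
    do_range: tuple[float, float] = (12.0, 6.0)
    rho_in_range: tuple[float, float] = (0.30, 0.80)
    env_noise_sd: float = 0.02


@dataclass
class SyntheticConfig:
    """Full description of one synthetic study."""

    n_groups: int = 7
    n_individuals_per_group: int = 30
    n_traits: int = 18
    n_modules: int = 3
    rho_out: float = 0.05
    cv_spec: dict[str, float] = field(default_factory=default_cv_spec)
    env_model: EnvModel = field(default_factory=EnvModel)
    noise_sd: float = 0.0  # extra independent noise added to each trait
    seed: int = 0
    trait_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.trait_names is None:
            if self.n_traits == len(DEFAULT_TRAITS):
                self.trait_names = DEFAULT_TRAITS
            else:
                self.trait_names = tuple(f"T{i+1}" for i in range(self.n_traits))
        if len(self.trait_names) != self.n_traits:
            raise ConfigurationError("trait_names length must equal n_traits")
        if not (0 <= self.rho_out <= min(self.env_model.rho_in_range) < 1):
            raise ConfigurationError(
                "need 0 <= rho_out <= rho_in < 1; got "
                f"rho_out={self.rho_out}, rho_in_range={self.env_model.rho_in_range}"
            )
        if self.n_modules < 1 or self.n_modules > self.n_traits:
            raise ConfigurationError("n_modules must be in [1, n_traits]")
        for t, cv in self.cv_spec.items():
            if cv <= 0:
                raise ConfigurationError(f"target CV for {t!r} must be > 0")

    def module_partition(self) -> np.ndarray:
        """Planted module label per trait (near-equal block sizes)."""
        return np.array(
            [i * self.n_modules // self.n_traits for i in range(self.n_traits)]
        )


@dataclass
class SyntheticDataset:
    """Generated data plus the ground truth that produced it."""

    trait_matrix: TraitMatrix
    env_table: EnvTable
    truth: dict


def block_correlation(
    partition: np.ndarray, rho_in: float, rho_out: float
) -> np.ndarray:
    """Correlation matrix with rho_in inside blocks, rho_out between.

    Validated positive semi-definite before use.
    """
    part = np.asarray(partition)
    same = part[:, None] == part[None, :]
    R = np.where(same, rho_in, rho_out)
    np.fill_diagonal(R, 1.0)
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < -1e-10:
        sizes = np.bincount(part)
        raise ConfigurationError(
            f"block correlation matrix not PSD (min eigenvalue {eigmin:.3g}) "
            f"for rho_in={rho_in}, rho_out={rho_out}, block sizes {sizes.tolist()}"
        )
    return R


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw the full synthetic study: trait matrix, environment, truth."""
    rng = np.random.default_rng(config.seed)
    part = config.module_partition()
    names = list(config.trait_names)
    cv = np.array([config.cv_spec.get(t, 0.3) for t in names])

    m = config.env_model
    u = (
        np.linspace(0.0, 1.0, config.n_groups)
        if config.n_groups > 1
        else np.array([0.5])
    )
    tp = m.tp_range[0] + (m.tp_range[1] - m.tp_range[0]) * u
    do = m.do_range[0] + (m.do_range[1] - m.do_range[0]) * u
    rho_in = m.rho_in_range[0] + (m.rho_in_range[1] - m.rho_in_range[0]) * u
    tp_obs = tp + rng.normal(0, m.env_noise_sd * abs(m.tp_range[1] - m.tp_range[0]),
                             size=tp.shape)
    do_obs = do + rng.normal(0, m.env_noise_sd * abs(m.do_range[1] - m.do_range[0]),
                             size=do.shape)

    blocks = []
    groups = []
    group_names = [f"WB{i+1}" for i in range(config.n_groups)]
    for g in range(config.n_groups):
        R = block_correlation(part, float(rho_in[g]), config.rho_out)
        L = np.linalg.cholesky(R + 1e-12 * np.eye(config.n_traits))
        z = rng.standard_normal((config.n_individuals_per_group, config.n_traits))
        x = z @ L.T
        if config.noise_sd > 0:
            x = x + rng.normal(0, config.noise_sd, size=x.shape)
        x = x + 1.0 / cv  # mean shift sets CV at fixed (unit) variance
        blocks.append(x)
        groups.extend([group_names[g]] * config.n_individuals_per_group)

    tm = TraitMatrix(
        values=np.vstack(blocks),
        trait_names=names,
        group=np.array(groups, dtype=object),
    )
    env = EnvTable(
        data=pd.DataFrame({"TP": tp_obs, "DO": do_obs}, index=group_names)
    )
    # linear coefficients of the rho_in-on-TP link implied by the shared gradient
    span = m.tp_range[1] - m.tp_range[0]
    slope = (m.rho_in_range[1] - m.rho_in_range[0]) / span if span else 0.0
    truth = {
        "module_partition": {t: int(p) for t, p in zip(names, part)},
        "rho_in": {g: float(r) for g, r in zip(group_names, rho_in)},
        "rho_out": config.rho_out,
        "cv_targets": {t: float(c) for t, c in zip(names, cv)},
        "env_coefficients": {
            "rho_in_on_TP": {
                "intercept": float(m.rho_in_range[0] - slope * m.tp_range[0]),
                "slope": float(slope),
            }
        },
        "seed": config.seed,
    }
    return SyntheticDataset(trait_matrix=tm, env_table=env, truth=truth)


def null_dataset(n_traits: int, n_individuals: int, seed: int) -> TraitMatrix:
    """Fully independent standard-normal traits: the type-I error harness.

    Under this null every trait pair is uncorrelated, so the expected
    fraction of significant pairs at level alpha is alpha.
    """
    if n_traits < 2:
        raise ConfigurationError("null dataset needs at least 2 traits")
    if n_individuals < 3:
        raise ConfigurationError(
            "null dataset needs at least 3 individuals for defined p-values"
        )
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_individuals, n_traits))
    return TraitMatrix(
        values=values,
        trait_names=[f"T{i+1}" for i in range(n_traits)],
        group=np.array(["null"] * n_individuals, dtype=object),
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write traits.csv / env.csv (the dialect trait_data reads) + truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traits_path = out_dir / "traits.csv"
    env_path = out_dir / "env.csv"
    truth_path = out_dir / "truth.json"
    ds.trait_matrix.to_frame().to_csv(traits_path, index=False)
    ds.env_table.data.rename_axis("group").reset_index().to_csv(env_path, index=False)
    truth_path.write_text(json.dumps(ds.truth, indent=2))
    return {"traits": traits_path, "env": env_path, "truth": truth_path}
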