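"""Run configuration: TOML file + command-line flag merging.

Precedence: flags override file values, file values override defaults.
All parameter constraints (alpha > beta, positive tolerance, ...) are
enforced at load so a bad configuration fails before any solve starts.

Example TOML::

    [model]
    alpha = 1.3
    beta = 0.1
    chroma_threshold = 0.05
    contour_threshold = 0.5
    display_gain = 1.0

    [solver]
    tolerance = 1e-6
    max_iterations = 50000
    method = "gauss_seidel"
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .solver import SolverConfig
from .zones import ModelParams

__all__ = ["RunConfig", "load_config"]

logger = logging.getLogger(__name__)

_MODEL_KEYS = {"alpha", "beta", "chroma_threshold", "contour_threshold", "display_gain"}
_SOLVER_KEYS = {"tolerance", "max_iterations", "method"}


@dataclass
class RunConfig:
    """Effective configuration of one run."""

    params: ModelParams = field(default_factory=ModelParams)
    out_dir: Path = Path(".")
    dump_intermediates: bool = False

    def log_effective(self) -> None:
        """Log the full effective configuration (reproducibility header)."""
        p, s = self.params, self.params.solver
        logger.info(
            "config: alpha=%g beta=%g chroma_threshold=%g contour_threshold=%g "
            "display_gain=%g solver=%s tolerance=%g max_iterations=%d out_dir=%s",
            p.alpha, p.beta, p.chroma_threshold, p.contour_threshold,
            p.display_gain, s.method, s.tolerance, s.max_iterations, self.out_dir,
        )


def _check_keys(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in [{name}]: {', '.join(sorted(unknown))}")


def load_config(
    path: str | Path | None = None,
    overrides: dict | None = None,
    out_dir: str | Path = ".",
    dump_intermediates: bool = False,
) -> RunConfig:
    """Build a RunConfig from an optional TOML file and flag overrides.

    ``overrides`` maps ModelParams/SolverConfig field names to values; a
    value of None means "flag not given".  Constraint violations raise
    ValueError naming the offending key.
    """
    model: dict = {}
    solver: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        _check_keys(data, {"model", "solver"}, "top level")
        model.update(data.get("model", {}))
        solver.update(data.get("solver", {}))
        _check_keys(model, _MODEL_KEYS, "model")
        _check_keys(solver, _SOLVER_KEYS, "solver")
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if key in _MODEL_KEYS:
            model[key] = value
        elif key in _SOLVER_KEYS:
            solver[key] = value
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    try:
        solver_cfg = SolverConfig(**solver)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid solver configuration: {exc}") from exc
    try:
        params = ModelParams(solver=solver_cfg, **model)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid model configuration: {exc}") from exc
    return RunConfig(
        params=params, out_dir=Path(out_dir), dump_intermediates=dump_intermediates
    )
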