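"""Run configuration: schema, validation and resolution.

A run is declared in one YAML file: the model (either the bundled obesity
model or an explicit state/term declaration), the parameter distributions,
chaos settings, the time grid and the requested analyses.  Validation
errors carry the dotted path of the offending field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .epidemic_model import PolynomialODEModel, RHSTerm, build_obesity_model
from .random_params import ParameterSet, RandomParameter, deterministic, uniform_about

__all__ = ["ConfigError", "RunConfig", "load_config", "resolve_config"]

ANALYSES = ("deterministic", "chaos", "sobol", "mc")


class ConfigError(ValueError):
    """Schema violation; ``path`` is the dotted location of the bad field."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved, validated run declaration."""

    model: PolynomialODEModel
    params: ParameterSet
    chaos_order: int
    t_end: float
    output_times: np.ndarray = field(repr=False)
    analyses: tuple[str, ...]
    mc_samples: int | None
    mc_seed: int | None
    mc_sobol_samples: int | None
    output_dir: str
    raw: dict = field(repr=False)


def _require(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise ConfigError(f"{path}.{key}", "required field is missing")
    return mapping[key]


def _as_number(value, path: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(path, f"expected a number, got {value!r}")
    return float(value)


def _as_int(value, path: str, minimum: int | None = None) -> int:
    if isinstance(value, bool) or not isinstance(value, int):
        raise ConfigError(path, f"expected an integer, got {value!r}")
    if minimum is not None and value < minimum:
        raise ConfigError(path, f"must be >= {minimum}, got {value}")
    return value


def _parse_parameters(section, path: str) -> ParameterSet:
    if not isinstance(section, dict) or not section:
        raise ConfigError(path, "expected a non-empty mapping of parameter declarations")
    params: list[RandomParameter] = []
    germ = 0
    for name, decl in section.items():
        ppath = f"{path}.{name}"
        if isinstance(decl, (int, float)) and not isinstance(decl, bool):
            params.append(deterministic(name, float(decl)))
        elif isinstance(decl, dict):
            dist = _require(decl, "dist", ppath)
            if dist == "uniform":
                lower = _as_number(_require(decl, "lower", ppath), f"{ppath}.lower")
                upper = _as_number(_require(decl, "upper", ppath), f"{ppath}.upper")
                if upper < lower:
                    raise ConfigError(f"{ppath}.upper", f"upper ({upper}) < lower ({lower})")
                params.append(RandomParameter(name, lower, upper, germ_dim=germ))
                germ += 1
            elif dist == "uniform_about":
                mean = _as_number(_require(decl, "mean", ppath), f"{ppath}.mean")
                params.append(uniform_about(name, mean, germ_dim=germ))
                germ += 1
            else:
                raise ConfigError(
                    f"{ppath}.dist", f"unknown distribution {dist!r} (uniform | uniform_about)"
                )
        else:
            raise ConfigError(ppath, f"expected a number or a distribution mapping, got {decl!r}")
    return ParameterSet.from_parameters(*params)


def _parse_terms(section, states, closure, path: str) -> dict[str, tuple[RHSTerm, ...]]:
    terms: dict[str, tuple[RHSTerm, ...]] = {}
    for state in states:
        tpath = f"{path}.{state}"
        tlist = section.get(state)
        if not isinstance(tlist, list) or not tlist:
            raise ConfigError(tpath, "expected a non-empty list of terms")
        parsed = []
        for k, t in enumerate(tlist):
            ipath = f"{tpath}[{k}]"
            if not isinstance(t, dict):
                raise ConfigError(ipath, f"expected a term mapping, got {t!r}")
            sign = _as_int(_require(t, "sign", ipath), f"{ipath}.sign")
            if sign not in (1, -1):
                raise ConfigError(f"{ipath}.sign", f"must be +1 or -1, got {sign}")
            names = t.get("params", [])
            if not isinstance(names, list) or not all(isinstance(n, str) for n in names):
                raise ConfigError(f"{ipath}.params", "expected a list of parameter names")
            const = _as_number(t.get("const", 1.0), f"{ipath}.const")
            monomial = t.get("states", [])
            if not isinstance(monomial, list) or len(monomial) > 2:
                raise ConfigError(f"{ipath}.states", "expected a list of at most 2 state names")
            parsed.append(RHSTerm(sign, tuple(names), const, tuple(monomial)))
        terms[state] = tuple(parsed)
    return terms


def _parse_model(section, params: ParameterSet, path: str) -> PolynomialODEModel:
    if not isinstance(section, dict):
        raise ConfigError(path, "expected a mapping")
    builtin = section.get("builtin")
    if builtin is not None:
        if builtin != "obesity":
            raise ConfigError(f"{path}.builtin", f"unknown builtin model {builtin!r}")
        variant = section.get("variant", "reduced")
        if variant not in ("full", "reduced"):
            raise ConfigError(f"{path}.variant", f"must be 'full' or 'reduced', got {variant!r}")
        try:
            return build_obesity_model(variant, params)
        except KeyError as exc:
            raise ConfigError("parameters", str(exc)) from None
    states_decl = _require(section, "states", path)
    if not isinstance(states_decl, dict) or not states_decl:
        raise ConfigError(f"{path}.states", "expected a mapping of state -> initial value")
    states = tuple(states_decl)
    initial = tuple(
        _as_number(v, f"{path}.states.{s}") for s, v in states_decl.items()
    )
    closure = section.get("closure")
    terms = _parse_terms(
        _require(section, "terms", path), states, closure, f"{path}.terms"
    )
    try:
        model = PolynomialODEModel(
            states=states, initial_values=initial, terms=terms, closure=closure
        )
        model.validate_parameters(params)
    except (ValueError, KeyError) as exc:
        raise ConfigError(path, str(exc)) from None
    return model


def resolve_config(raw: dict) -> RunConfig:
    """Validate a parsed configuration mapping and resolve it to objects."""
    if not isinstance(raw, dict):
        raise ConfigError("<root>", "configuration must be a mapping")

    params = _parse_parameters(_require(raw, "parameters", "<root>"), "parameters")
    model = _parse_model(_require(raw, "model", "<root>"), params, "model")

    analyses_raw = _require(raw, "analyses", "<root>")
    if not isinstance(analyses_raw, list) or not analyses_raw:
        raise ConfigError("analyses", "expected a non-empty list")
    for a in analyses_raw:
        if a not in ANALYSES:
            raise ConfigError("analyses", f"unknown analysis {a!r} (choose from {ANALYSES})")
    analyses = tuple(dict.fromkeys(analyses_raw))

    chaos_section = raw.get("chaos", {})
    if not isinstance(chaos_section, dict):
        raise ConfigError("chaos", "expected a mapping")
    chaos_order = _as_int(chaos_section.get("order", 2), "chaos.order")
    if ("chaos" in analyses or "sobol" in analyses) and chaos_order < 1:
        raise ConfigError("chaos.order", f"must be >= 1 when chaos/sobol is requested, got {chaos_order}")

    time_section = _require(raw, "time", "<root>")
    if not isinstance(time_section, dict):
        raise ConfigError("time", "expected a mapping")
    t_end = _as_number(_require(time_section, "t_end", "time"), "time.t_end")
    if t_end <= 0:
        raise ConfigError("time.t_end", f"must be positive, got {t_end}")
    stride = _as_number(time_section.get("stride", max(t_end / 200.0, 1.0)), "time.stride")
    if stride <= 0:
        raise ConfigError("time.stride", f"must be positive, got {stride}")
    times = np.arange(0.0, t_end + 0.5 * stride, stride)
    extra = time_section.get("extra_times", [])
    if not isinstance(extra, list):
        raise ConfigError("time.extra_times", "expected a list of times")
    for i, t in enumerate(extra):
        tv = _as_number(t, f"time.extra_times[{i}]")
        if not 0.0 <= tv <= t_end:
            raise ConfigError(f"time.extra_times[{i}]", f"{tv} outside [0, {t_end}]")
    output_times = np.unique(np.concatenate([times, np.asarray(extra, dtype=float)]))

    mc_section = raw.get("mc", {})
    if not isinstance(mc_section, dict):
        raise ConfigError("mc", "expected a mapping")
    mc_samples = mc_seed = mc_sobol_samples = None
    if "mc" in analyses:
        mc_samples = _as_int(_require(mc_section, "n_samples", "mc"), "mc.n_samples", minimum=2)
        mc_seed = _as_int(_require(mc_section, "seed", "mc"), "mc.seed", minimum=0)
        mc_sobol_samples = _as_int(
            mc_section.get("sobol_samples", mc_samples), "mc.sobol_samples", minimum=100
        )

    output_dir = raw.get("output_dir", "epichaos_out")
    if not isinstance(output_dir, str) or not output_dir:
        raise ConfigError("output_dir", "expected a non-empty path string")

    return RunConfig(
        model=model,
        params=params,
        chaos_order=chaos_order,
        t_end=t_end,
        output_times=output_times,
        analyses=analyses,
        mc_samples=mc_samples,
        mc_seed=mc_seed,
        mc_sobol_samples=mc_sobol_samples,
        output_dir=output_dir,
        raw=raw,
    )


def load_config(path) -> RunConfig:
    """Read and resolve a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return resolve_config(raw)
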