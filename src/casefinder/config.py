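"""YAML run configuration.

A run is fully reproducible from one YAML file plus one seed: the file
declares the analysis windows, generator parameters, algorithm expressions,
code-set overrides, prevalence band and population denominators.  Every key
is optional except where noted; unknown keys raise, so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping

import yaml

from . import vocab
from .engine import AlgorithmSpec, builtin_algorithms, parse_algorithm
from .model import AnalysisWindow, CodeSet, financial_year
from .pipeline import PipelineSettings
from .prevalence import DEFAULT_BAND, Denominator, PrevalenceBand, derive_band
from .synthetic import DEFAULT_ATOM_NOISE, AtomNoise, GeneratorConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int
    mode: str
    windows: list[AnalysisWindow]
    generator: GeneratorConfig
    specs: list[AlgorithmSpec]
    settings: PipelineSettings
    band: PrevalenceBand
    denominators: dict[str, Denominator]
    rounding: str = "half-up"
    tables_dir: Path = Path("data")
    out_dir: Path = Path("out")

    def generator_for(self, window: AnalysisWindow, index: int) -> GeneratorConfig:
        """Per-window generator: same parameters, window-specific sub-seed."""
        from dataclasses import replace

        return replace(self.generator, window=window,
                       seed=(self.seed + index) % 2**31)


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise ValueError(f"config error: missing key {key!r} in {context}")
    return mapping[key]


def _check_keys(mapping: Mapping, allowed: set[str], context: str) -> None:
    extra = set(mapping) - allowed
    if extra:
        raise ValueError(
            f"config error: unknown key(s) {sorted(extra)} in {context}"
        )


def _parse_window(obj, context: str) -> AnalysisWindow:
    if isinstance(obj, int):
        return financial_year(obj)
    if not isinstance(obj, Mapping):
        raise ValueError(f"config error: {context} must be a mapping or a year")
    if "financial_year" in obj:
        return financial_year(int(obj["financial_year"]))
    _check_keys(obj, {"label", "start", "end"}, context)
    start, end = _require(obj, "start", context), _require(obj, "end", context)
    if not isinstance(start, date) or not isinstance(end, date):
        raise ValueError(f"config error: {context} dates must be ISO dates")
    return AnalysisWindow(str(obj.get("label", f"{start}..{end}")), start, end)


def _parse_codeset(obj: Mapping, name: str) -> CodeSet:
    _check_keys(obj, {"codes", "match_mode"}, f"codesets.{name}")
    codes = _require(obj, "codes", f"codesets.{name}")
    return CodeSet(name, frozenset(codes), obj.get("match_mode", "exact"))


def _parse_generator(obj: Mapping, windows: list[AnalysisWindow],
                     seed: int) -> GeneratorConfig:
    _check_keys(obj, {"n_patients", "true_prevalence", "age_bands", "atom_noise",
                      "comorbid_dementia_prob", "shared_severity_rho"},
                "generator")
    noise = dict(DEFAULT_ATOM_NOISE)
    for atom, spec in (obj.get("atom_noise") or {}).items():
        _check_keys(spec, {"sens", "fpr"}, f"generator.atom_noise.{atom}")
        noise[atom] = AtomNoise(float(spec["sens"]), float(spec["fpr"]))
    kwargs = dict(
        n_patients=int(obj.get("n_patients", 50_000)),
        true_prevalence=float(obj.get("true_prevalence", 0.003)),
        window=windows[0],
        atom_noise=noise,
        comorbid_dementia_prob=float(obj.get("comorbid_dementia_prob", 0.05)),
        shared_severity_rho=float(obj.get("shared_severity_rho", 0.0)),
        seed=seed,
    )
    if "age_bands" in obj:
        kwargs["age_bands"] = tuple(
            (int(lo), int(hi), float(w)) for lo, hi, w in obj["age_bands"]
        )
    return GeneratorConfig(**kwargs)


def _parse_band(obj: Mapping) -> PrevalenceBand:
    if "base" in obj:
        _check_keys(obj, {"base", "low_chain", "high_chain"}, "screen.band")
        return derive_band(float(obj["base"]),
                           [float(f) for f in _require(obj, "low_chain", "screen.band")],
                           [float(f) for f in _require(obj, "high_chain", "screen.band")])
    _check_keys(obj, {"low", "high"}, "screen.band")
    return PrevalenceBand(float(_require(obj, "low", "screen.band")),
                          float(_require(obj, "high", "screen.band")))


def load_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as e:
        raise ValueError(f"config error: {path} is not valid YAML: {e}") from e
    if not isinstance(raw, Mapping):
        raise ValueError(f"config error: {path} must contain a mapping")
    _check_keys(raw, {"seed", "mode", "windows", "generator", "algorithms",
                      "codesets", "screen", "paths", "honos_threshold",
                      "strict_older_exclusion"}, "top level")

    seed = int(seed_override if seed_override is not None else raw.get("seed", 0))
    mode = str(raw.get("mode", "prevalent"))
    if mode not in ("incident", "prevalent"):
        raise ValueError(f"config error: mode must be incident|prevalent, got {mode!r}")

    windows = [_parse_window(w, f"windows[{i}]")
               for i, w in enumerate(raw.get("windows", [2018]))]
    if not windows:
        raise ValueError("config error: windows list is empty")

    generator = _parse_generator(raw.get("generator") or {}, windows, seed)

    codesets = {name: _parse_codeset(obj, name)
                for name, obj in (raw.get("codesets") or {}).items()}
    known_cs = {"psychosis", "psychosis_clusters", "dementia",
                "psychotic_depression"}
    _check_keys(codesets, known_cs, "codesets")
    settings = PipelineSettings(
        psychosis_codeset=codesets.get("psychosis", vocab.PSYCHOSIS_ICD10),
        cluster_codeset=codesets.get("psychosis_clusters", vocab.PSYCHOSIS_CLUSTERS),
        honos_threshold=int(raw.get("honos_threshold", vocab.HONOS_THRESHOLD)),
        exclusion_codesets=(
            codesets.get("dementia", vocab.DEMENTIA_ICD10),
            codesets.get("psychotic_depression", vocab.PSYCHOTIC_DEPRESSION_ICD10),
        ),
        strict_older_exclusion=bool(raw.get("strict_older_exclusion", False)),
    )

    algo = raw.get("algorithms") or {}
    _check_keys(algo, {"builtin", "extra"}, "algorithms")
    specs: list[AlgorithmSpec] = []
    if algo.get("builtin", True):
        specs.extend(builtin_algorithms(mode))
    for i, entry in enumerate(algo.get("extra") or []):
        _check_keys(entry, {"id", "expression", "mode"}, f"algorithms.extra[{i}]")
        specs.append(parse_algorithm(
            _require(entry, "expression", f"algorithms.extra[{i}]"),
            id=str(entry.get("id", f"X{i + 1}")),
            mode=str(entry.get("mode", mode)),
        ))
    if not specs:
        raise ValueError("config error: no algorithms configured")

    scr = raw.get("screen") or {}
    _check_keys(scr, {"band", "denominators", "rounding"}, "screen")
    band = _parse_band(scr["band"]) if "band" in scr else DEFAULT_BAND
    rounding = str(scr.get("rounding", "half-up"))
    denominators: dict[str, Denominator] = {}
    for i, d in enumerate(scr.get("denominators") or []):
        _check_keys(d, {"window", "population", "source"},
                    f"screen.denominators[{i}]")
        label = str(_require(d, "window", f"screen.denominators[{i}]"))
        denominators[label] = Denominator(
            label, int(_require(d, "population", f"screen.denominators[{i}]")),
            str(d.get("source", "")),
        )
    # synthetic self-contained default: the generated population itself
    for w in windows:
        denominators.setdefault(
            w.label,
            Denominator(w.label, max(generator.n_patients, 1),
                        "generated population"),
        )

    paths = raw.get("paths") or {}
    _check_keys(paths, {"tables_dir", "out_dir"}, "paths")
    return RunConfig(
        seed=seed, mode=mode, windows=windows, generator=generator,
        specs=specs, settings=settings, band=band, denominators=denominators,
        rounding=rounding,
        tables_dir=Path(paths.get("tables_dir", "data")),
        out_dir=Path(paths.get("out_dir", "out")),
    )
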