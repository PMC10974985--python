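"""Plain-text configuration for the pipeline.

INI-style key-value file with sections ``[child]``, ``[adult]``, ``[rfd]``,
``[background]``, ``[pmf]``, ``[synthetic]`` and ``[risk]``.  Absent
sections or keys fall back to the packaged defaults (the published exposure
parameters and reference doses; world-soil backgrounds; the generator and
solver defaults), and the log records which values came from the file.
Unknown keys are rejected with the list of valid keys.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

from .datamodel import (
    BackgroundTable,
    ExposureParameters,
    RfDTable,
    ValidationError,
    default_background,
    default_rfd,
    PATHWAYS,
)
from .synthetic import SyntheticSpec

logger = logging.getLogger(__name__)

_RECEPTOR_KEYS = (
    "ingestion_rate",
    "skin_area",
    "skin_adherence",
    "dermal_absorption",
    "inhalation_rate",
    "particle_emission_factor",
    "exposure_frequency",
    "exposure_duration",
    "body_weight",
    "averaging_time_noncarcinogenic",
    "averaging_time_carcinogenic",
    "conversion_factor",
    "volatilization_factor",
)

_PMF_KEYS = ("k_candidates", "seeds", "max_iter", "tol")
_SYNTH_KEYS = ("n_sites", "k_true", "noise_cv", "seed")
_RISK_KEYS = ("use_printed_inhalation_formula",)


@dataclass
class PMFOptions:
    k_candidates: tuple[int, ...] = (3, 4, 5)
    seeds: int = 20
    max_iter: int = 5000
    tol: float = 1e-8


@dataclass
class RunConfig:
    child: ExposureParameters = field(default_factory=ExposureParameters.child_default)
    adult: ExposureParameters = field(default_factory=ExposureParameters.adult_default)
    rfd: RfDTable = field(default_factory=default_rfd)
    background: BackgroundTable = field(default_factory=default_background)
    pmf: PMFOptions = field(default_factory=PMFOptions)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    use_printed_inhalation_formula: bool = False


def _check_keys(section: str, keys, valid) -> None:
    unknown = [k for k in keys if k not in valid]
    if unknown:
        raise ValidationError(
            f"unknown key(s) {unknown} in section [{section}]; valid keys: {sorted(valid)}"
        )


def _receptor_from_section(name: str, section) -> ExposureParameters:
    defaults = (
        ExposureParameters.child_default()
        if name == "child"
        else ExposureParameters.adult_default()
    )
    _check_keys(name, section.keys(), _RECEPTOR_KEYS)
    kwargs = {f.name: getattr(defaults, f.name) for f in dc_fields(defaults)}
    for key in section:
        kwargs[key] = float(section[key])
        logger.info("config: [%s] %s = %s (from file)", name, key, kwargs[key])
    if "exposure_duration" in section and "averaging_time_noncarcinogenic" not in section:
        kwargs["averaging_time_noncarcinogenic"] = kwargs["exposure_duration"] * 365.0
        logger.info(
            "config: [%s] averaging_time_noncarcinogenic recomputed as %s",
            name,
            kwargs["averaging_time_noncarcinogenic"],
        )
    return ExposureParameters(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load configuration, falling back to packaged defaults everywhere.

    ``path=None`` returns the pure defaults.
    """
    cfg = RunConfig()
    if path is None:
        logger.info("config: no file given, using packaged defaults throughout")
        return cfg
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = configparser.ConfigParser()
    parser.optionxform = str  # keep element symbols case-sensitive
    parser.read(path)

    known_sections = {"child", "adult", "rfd", "background", "pmf", "synthetic", "risk"}
    unknown = set(parser.sections()) - known_sections
    if unknown:
        raise ValidationError(
            f"unknown section(s) {sorted(unknown)}; valid: {sorted(known_sections)}"
        )

    if parser.has_section("child"):
        cfg.child = _receptor_from_section("child", parser["child"])
    if parser.has_section("adult"):
        cfg.adult = _receptor_from_section("adult", parser["adult"])

    if parser.has_section("rfd"):
        table = {el: dict(p) for el, p in cfg.rfd.values.items()}
        valid = {f"{el}_{pw}" for el in list(table) + ["Sc", "Rb"] for pw in PATHWAYS}
        _check_keys("rfd", parser["rfd"].keys(), valid)
        for key, raw in parser["rfd"].items():
            el, pw = key.rsplit("_", 1)
            if raw.strip() in ("-", "none", ""):
                table.setdefault(el, {}).pop(pw, None)
            else:
                table.setdefault(el, {})[pw] = float(raw)
            logger.info("config: [rfd] %s = %s (from file)", key, raw)
        cfg.rfd = RfDTable(table)

    if parser.has_section("background"):
        bg = dict(cfg.background.values)
        for el, raw in parser["background"].items():
            bg[el] = float(raw)
            logger.info("config: [background] %s = %s (from file)", el, raw)
        cfg.background = BackgroundTable(bg)

    if parser.has_section("pmf"):
        _check_keys("pmf", parser["pmf"].keys(), _PMF_KEYS)
        sec = parser["pmf"]
        cfg.pmf = PMFOptions(
            k_candidates=tuple(
                int(x) for x in sec.get("k_candidates", "3,4,5").split(",")
            ),
            seeds=int(sec.get("seeds", "20")),
            max_iter=int(sec.get("max_iter", "5000")),
            tol=float(sec.get("tol", "1e-8")),
        )
        for key in sec:
            logger.info("config: [pmf] %s = %s (from file)", key, sec[key])

    if parser.has_section("synthetic"):
        sec = parser["synthetic"]
        valid = set(_SYNTH_KEYS) | {f"range_{el}" for el in cfg.synthetic.elements}
        _check_keys("synthetic", sec.keys(), valid)
        ranges = dict(cfg.synthetic.calibration_ranges)
        kwargs = {}
        for key in sec:
            if key.startswith("range_"):
                lo, hi = (float(x) for x in sec[key].split(","))
                ranges[key[len("range_"):]] = (lo, hi)
            elif key in ("n_sites", "k_true", "seed"):
                kwargs[key] = int(sec[key])
            else:
                kwargs[key] = float(sec[key])
            logger.info("config: [synthetic] %s = %s (from file)", key, sec[key])
        cfg.synthetic = SyntheticSpec(calibration_ranges=ranges, **kwargs)

    if parser.has_section("risk"):
        _check_keys("risk", parser["risk"].keys(), _RISK_KEYS)
        cfg.use_printed_inhalation_formula = parser["risk"].getboolean(
            "use_printed_inhalation_formula", False
        )

    return cfg
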