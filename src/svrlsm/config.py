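"""Run configuration: schema validation with aggregated error reporting.

The YAML config mirrors the pipeline stages::

    paths:        {masks, spans, detections, atlas, output}
    behavior:     {correction, threshold}
    lesions:      {min_subjects}
    grid:         {cost_min, cost_max, gamma_min, gamma_max, epsilon}
    permutations: {n}
    alpha: 0.05
    seed: 0

Every omitted field is filled with its default and logged with its
provenance (study default vs. package choice).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import yaml

logger = logging.getLogger("svrlsm")

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  " + "\n  ".join(problems))


# (default, provenance) per dotted key; provenance distinguishes values the
# study protocol fixes from package-level choices.
_SCHEMA = {
    "paths.masks": (None, "required for run-lsm"),
    "paths.spans": (None, "required for run-lsm"),
    "paths.detections": (None, "required for run-lsm"),
    "paths.atlas": (None, "optional"),
    "paths.output": ("lsm_output", "package choice"),
    "behavior.correction": ("half_trial", "reproduces the d' ceiling 3.78"),
    "behavior.threshold": (0.75, "study protocol"),
    "lesions.min_subjects": (5, "study protocol"),
    "grid.cost_min": (1e-2, "study protocol"),
    "grid.cost_max": (1e9, "study protocol"),
    "grid.gamma_min": (1e-9, "study protocol"),
    "grid.gamma_max": (1e3, "study protocol"),
    "grid.epsilon": (0.1, "package choice (libsvm default)"),
    "permutations.n": (1000, "study protocol"),
    "alpha": (0.05, "study protocol"),
    "seed": (0, "package choice"),
}


@dataclass(frozen=True)
class RunConfig:
    paths: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)
    lesions: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    permutations: dict = field(default_factory=dict)
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _get(raw: dict, dotted: str):
    cur = raw
    for part in dotted.split("."):
        if not isinstance(cur, dict) or part not in cur:
            return None, False
        cur = cur[part]
    return cur, True


def validate_config(raw: dict | None) -> RunConfig:
    """Schema-check a raw mapping, fill defaults, aggregate every problem.

    Unknown keys and out-of-range values are reported together in one
    :class:`ConfigError` rather than failing at the first problem.
    """
    raw = dict(raw or {})
    problems: list[str] = []

    known_top = {"paths", "behavior", "lesions", "grid", "permutations", "alpha", "seed"}
    for key in raw:
        if key not in known_top:
            problems.append(f"unknown key {key!r}")
    known_nested: dict[str, set] = {}
    for dotted in _SCHEMA:
        if "." in dotted:
            sec, leaf = dotted.split(".", 1)
            known_nested.setdefault(sec, set()).add(leaf)
    for sec, leaves in known_nested.items():
        sub = raw.get(sec)
        if sub is None:
            continue
        if not isinstance(sub, dict):
            problems.append(f"section {sec!r} must be a mapping")
            continue
        for key in sub:
            if key not in leaves:
                problems.append(f"unknown key {sec}.{key}")

    filled: dict = {}
    for dotted, (default, provenance) in _SCHEMA.items():
        value, present = _get(raw, dotted)
        if not present:
            value = default
            if default is not None:
                logger.debug("config %s defaulted to %r (%s)", dotted, default, provenance)
        cur = filled
        parts = dotted.split(".")
        for part in parts[:-1]:
            cur = cur.setdefault(part, {})
        cur[parts[-1]] = value

    def check(cond: bool, msg: str):
        if not cond:
            problems.append(msg)

    alpha = filled["alpha"]
    check(isinstance(alpha, (int, float)) and 0 < alpha < 1, f"alpha={alpha!r} not in (0, 1)")
    seed = filled["seed"]
    check(isinstance(seed, int) and 0 <= seed < 2**31, f"seed={seed!r} not an int in [0, 2^31)")
    n_perm = filled["permutations"]["n"]
    check(isinstance(n_perm, int) and n_perm >= 1, f"permutations.n={n_perm!r} must be >= 1")
    ms = filled["lesions"]["min_subjects"]
    check(
        isinstance(ms, (int, float)) and ms > 0,
        f"lesions.min_subjects={ms!r} must be positive",
    )
    thr = filled["behavior"]["threshold"]
    check(
        isinstance(thr, (int, float)) and 0.5 < thr < 1.0,
        f"behavior.threshold={thr!r} not in (0.5, 1.0)",
    )
    check(
        filled["behavior"]["correction"] in ("half_trial", "none"),
        f"behavior.correction={filled['behavior']['correction']!r} unknown",
    )
    g = filled["grid"]
    for lo, hi in (("cost_min", "cost_max"), ("gamma_min", "gamma_max")):
        check(
            isinstance(g[lo], (int, float)) and isinstance(g[hi], (int, float))
            and 0 < g[lo] <= g[hi],
            f"grid bounds {lo}..{hi} invalid: {g[lo]!r}..{g[hi]!r}",
        )
    check(
        isinstance(g["epsilon"], (int, float)) and g["epsilon"] >= 0,
        f"grid.epsilon={g['epsilon']!r} must be >= 0",
    )

    if problems:
        raise ConfigError(problems)
    return RunConfig(
        paths=filled["paths"],
        behavior=filled["behavior"],
        lesions=filled["lesions"],
        grid=filled["grid"],
        permutations=filled["permutations"],
        alpha=float(alpha),
        seed=int(seed),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)
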