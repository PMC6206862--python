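"""Trait vocabulary and breeding-direction conventions.

The ten yield/fiber traits of an upland-cotton L×T trial: PH plant height,
BW boll weight, LP lint percentage, BN bolls per plant, FL fiber length
(upper-half mean), FS fiber strength, MIC micronaire, FU fiber uniformity,
FE fiber elongation, FUI fiber uniformity index.

Micronaire measures fiber fineness: finer fiber (lower MIC) is preferred,
so its desired direction is -1; all other traits are improved upward.
"""

from __future__ import annotations

TRAITS: tuple[str, ...] = ("PH", "BW", "LP", "BN", "FL", "FS", "MIC", "FU", "FE", "FUI")

#: +1 = higher is better, -1 = lower is better.
DEFAULT_DIRECTIONS: dict[str, int] = {t: 1 for t in TRAITS}
DEFAULT_DIRECTIONS["MIC"] = -1

#: The five heterosis statistics computed per cross x trait.
HETEROSIS_METRICS: tuple[str, ...] = ("MP", "HB", "HI", "K3", "K4")

#: Dependent-variable names used in association scans.
VARIABLES: tuple[str, ...] = ("phenotype", "GCA", "SCA", "HB", "HI", "MP", "K3", "K4")

#: Variables indicating dominance when supporting a stable QTL.
DOMINANCE_VARIABLES: frozenset[str] = frozenset({"SCA", "HB", "HI", "MP", "K3", "K4"})


def check_direction_table(directions: dict[str, int]) -> dict[str, int]:
    from .errors import ConfigError

    for t, d in directions.items():
        if t not in TRAITS:
            raise ConfigError(f"directions: unknown trait code {t!r}")
        if d not in (-1, 1):
            raise ConfigError(f"directions[{t}]: must be +1 or -1, got {d!r}")
    return directions
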