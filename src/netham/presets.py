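"""Published model presets for the five amyloid fibril topologies.

Each preset is a phi vector (physical form, kB*T = 1) over the nine
statistics edges, 2-star, NSP1, NSP2, ESP0, ESP1, 5-cycle, 6-cycle,
7-cycle, discovered by genetic-algorithm optimization of fibril yield.
``get_preset`` trims zero-coefficient statistics by default, since a
statistic with coefficient zero leaves the model distribution unchanged
and only slows sampling.
"""

from __future__ import annotations

from .fibril_assay import TEMPLATES, FibrilTemplate
from .hamiltonian import ModelSpec, PhiVector
from .netstats import StatSpec

__all__ = ["PRESET_NAMES", "get_preset", "preset_template"]

_FULL_SPEC = StatSpec(
    ("edges", "twostar", "nsp1", "nsp2", "esp0", "esp1", "cycle5", "cycle6", "cycle7")
)

# rows: edges, twostar, nsp1, nsp2, esp0, esp1, cycle5, cycle6, cycle7
_PRESETS: dict[str, tuple[float, ...]] = {
    "1-ribbon": (-107.22, 37.33, 1.35, 0, 0, 0, 0, 0, 0),
    "2-ribbon": (-102.28, 25.2, -0.44, -5.56, 0, 0, 0, 0, 0),
    "1,2 2-ribbon": (-158.21, 27.28, 1.87, -7.12, 6.59, 0, 0, 0, 0),
    "double 1,2 2-ribbon": (-471.95, 65.31, -0.25, -23.99, 75.18, 62.03, 0, 0, 0),
    "3-prism": (-193.35, 38.13, -5.77, -14.7, -2.51, -11.14, 0.12, 0.69, -0.02),
}

PRESET_NAMES: tuple[str, ...] = tuple(_PRESETS)

_ALIASES = {
    "1ribbon": "1-ribbon",
    "2ribbon": "2-ribbon",
    "12-2-ribbon": "1,2 2-ribbon",
    "1,2-2-ribbon": "1,2 2-ribbon",
    "122ribbon": "1,2 2-ribbon",
    "double-1,2-2-ribbon": "double 1,2 2-ribbon",
    "double122ribbon": "double 1,2 2-ribbon",
    "3prism": "3-prism",
}


def _canonical(name: str) -> str:
    key = name.strip().lower()
    if key in _PRESETS:
        return key
    if key in _ALIASES:
        return _ALIASES[key]
    raise KeyError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")


def get_preset(name: str, *, trim_zeros: bool = True) -> ModelSpec:
    """Load a published model by fibril-topology name.

    With ``trim_zeros`` (default) statistics whose coefficient is exactly
    zero are dropped from the statistic set; set it False to keep the full
    nine-statistic vector.
    """
    key = _canonical(name)
    row = _PRESETS[key]
    if trim_zeros:
        pairs = [(n, x) for n, x in zip(_FULL_SPEC.names, row) if x != 0]
    else:
        pairs = list(zip(_FULL_SPEC.names, row))
    spec = StatSpec([n for n, _ in pairs])
    phi = PhiVector(spec, {n: x for n, x in pairs})
    return ModelSpec(spec=spec, phi=phi, name=key)


def preset_template(name: str) -> FibrilTemplate:
    """The fibril template a preset was optimized to produce."""
    return TEMPLATES[_canonical(name)]
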