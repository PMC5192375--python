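"""Registry of published optimal parameter sets for the six event types.

Each preset is the rank-1 solution of a brute-force multi-objective search
maximising the mean of sensitivity and positive predictivity on an
annotated training database for that event type.  They are intended to
work "out of the box" across sampling frequencies, since all windows are
expressed in milliseconds and the band edges in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import TermaParams

__all__ = ["PresetEntry", "get_preset", "list_presets", "register_preset"]


@dataclass(frozen=True)
class PresetEntry:
    name: str
    params: TermaParams
    event_label: str
    source_note: str


_SHIPPED: dict[str, PresetEntry] = {
    p.name: p
    for p in [
        PresetEntry(
            name="ecg-qrs",
            params=TermaParams(F1=8, F2=20, W1_ms=97, W2_ms=611, beta=0.08),
            event_label="ECG QRS complex",
            source_note="optimal Pareto solution, trained on an annotated arrhythmia ECG database",
        ),
        PresetEntry(
            name="ecg-twave",
            params=TermaParams(F1=0.5, F2=10, W1_ms=70, W2_ms=140, beta=0.0),
            event_label="ECG T wave",
            source_note="optimal Pareto solution, trained on an annotated QT-interval ECG database",
        ),
        PresetEntry(
            name="ppg-systolic",
            params=TermaParams(F1=0.5, F2=8, W1_ms=111, W2_ms=667, beta=0.02),
            event_label="PPG systolic wave",
            source_note="optimal Pareto solution, trained on a heat-stress PPG database",
        ),
        PresetEntry(
            name="apg-ab",
            params=TermaParams(F1=0.5, F2=15, W1_ms=175, W2_ms=1000, beta=0.0),
            event_label="APG a and b waves",
            source_note="optimal Pareto solution, trained on a heat-stress APG database",
        ),
        PresetEntry(
            name="apg-cde",
            params=TermaParams(F1=0.5, F2=7, W1_ms=5, W2_ms=15, beta=0.0),
            event_label="APG c, d and e waves",
            source_note="optimal Pareto solution, trained on a heat-stress APG database",
        ),
        PresetEntry(
            name="heart-sounds",
            params=TermaParams(F1=0, F2=60, W1_ms=130, W2_ms=270, beta=0.03),
            event_label="heart sounds S1 and S2",
            source_note="optimal Pareto solution, trained on a digital-stethoscope heart-sound database",
        ),
    ]
}

_USER: dict[str, PresetEntry] = {}


def get_preset(name: str) -> PresetEntry:
    """Return the preset registered under ``name``.

    Raises ``KeyError`` listing the available names when unknown.
    """
    for registry in (_SHIPPED, _USER):
        if name in registry:
            return registry[name]
    available = ", ".join(sorted({**_SHIPPED, **_USER}))
    raise KeyError(f"unknown preset {name!r}; available: {available}")


def list_presets() -> list[PresetEntry]:
    """All shipped and user-registered presets, sorted by name."""
    merged = {**_SHIPPED, **_USER}
    return [merged[k] for k in sorted(merged)]


def register_preset(entry: PresetEntry) -> None:
    """Register a user preset; shipped names cannot be overridden."""
    if entry.name in _SHIPPED:
        raise ValueError(f"cannot override shipped preset {entry.name!r}")
    _USER[entry.name] = entry
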