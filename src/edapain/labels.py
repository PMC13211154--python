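"""Pain-class labels shared by every module."""

from __future__ import annotations

import enum


class Label(enum.IntEnum):
    """Three-level pain intensity: the class index doubles as the
    output-neuron index of every classifier in the package."""

    NO_PAIN = 0
    LOW_PAIN = 1
    HIGH_PAIN = 2

    def __str__(self) -> str:  # CSV-friendly name
        return {0: "NoPain", 1: "LowPain", 2: "HighPain"}[self.value]

    @classmethod
    def from_string(cls, s: str) -> "Label":
        try:
            return {"NoPain": cls.NO_PAIN, "LowPain": cls.LOW_PAIN, "HighPain": cls.HIGH_PAIN}[s]
        except KeyError:
            raise ValueError(f"unknown pain label {s!r}; expected NoPain/LowPain/HighPain") from None


CLASS_NAMES = [str(Label(i)) for i in range(3)]
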