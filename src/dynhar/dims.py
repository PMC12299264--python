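"""Shared architecture-dimension container."""

from __future__ import annotations

from dataclasses import dataclass

ARCHS = ("firnn", "lstm", "gru")


@dataclass(frozen=True)
class ArchDims:
    """Architecture dimensions: inputs, delays, hidden units, classes.

    ``nd`` (delays) is the number of FIR taps for the FIRNN and the
    consumed input-sequence length for LSTM/GRU.
    """

    ni: int
    nd: int
    nh: int
    nc: int

    def validate(self) -> None:
        for name in ("ni", "nd", "nh", "nc"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 1:
                raise ValueError(f"ArchDims.{name} must be a positive integer, got {v!r}")
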