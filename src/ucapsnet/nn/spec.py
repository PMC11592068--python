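"""Queryable architecture descriptions.

A :class:`NetworkSpec` is a flat, ordered list of layer descriptors (kind,
output shape, parameter count) plus a name-based query interface.  It is the
surface on which architecture tests assert printed shape/parameter traces
without touching any weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence


@dataclass(frozen=True)
class LayerInfo:
    """One layer of a network: its kind, output shape and parameter count.

    ``params`` counts every parameter stored by the layer, including
    non-trainable batch-norm moving statistics (the convention used by the
    summary printers of the major deep-learning frameworks).
    """

    name: str
    kind: str
    output_shape: tuple[int, ...]
    params: int


class NetworkSpec:
    """Ordered collection of :class:`LayerInfo` with name lookup."""

    def __init__(self, name: str, layers: Sequence[LayerInfo]):
        self.name = name
        self._layers = list(layers)
        self._by_name = {li.name: li for li in self._layers}
        if len(self._by_name) != len(self._layers):
            raise ValueError("duplicate layer names in network spec")

    @property
    def total_parameters(self) -> int:
        return sum(li.params for li in self._layers)

    def layer(self, name: str) -> LayerInfo:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no layer named {name!r} in {self.name}") from None

    def __iter__(self) -> Iterator[LayerInfo]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def table(self) -> str:
        """Render the trace as a plain-text table (layer, shape, params)."""
        rows = [("layer", "kind", "output shape", "params")]
        for li in self._layers:
            shape = "(" + ", ".join(str(d) for d in li.output_shape) + ")"
            rows.append((li.name, li.kind, shape, f"{li.params:,}"))
        rows.append(("total", "", "", f"{self.total_parameters:,}"))
        widths = [max(len(r[i]) for r in rows) for i in range(4)]
        lines = []
        for i, r in enumerate(rows):
            lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip())
            if i == 0:
                lines.append("-" * (sum(widths) + 6))
        return "\n".join(lines)
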