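"""Closed-form receptive-field and parameter-count calculators.

These identities drive two things: the ``params`` report (how big each
architectural component is, in parameters and serialized megabytes) and
the test oracles that check the constructed network against arithmetic.

For a square kernel of side ``k`` dilated by ``d`` the effective kernel is

    k' = k + (k - 1)(d - 1)

and the receptive field of a chain of layers grows as

    RF_{i+1} = RF_i + (k'_i - 1) * S_i,     RF_0 = 1,

where ``S_i`` is the product of the strides of all preceding layers.

Parameter counts follow the standard factorization: a full convolution
holds k*k*C_in*C_out weights, a depthwise-separable one holds
k*k*C_in (depthwise stage) + C_in*C_out (1x1 pointwise stage), so their
ratio tends to 1/C_out + 1/k^2 as channel counts grow.

Serialized size uses decimal megabytes at 32-bit precision:
``count * 4 / 10**6`` — the only convention under which per-component
sizes add up the way the package reports them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

__all__ = [
    "ConvSpec",
    "LayerChain",
    "ParamReport",
    "effective_kernel_size",
    "cumulative_stride",
    "receptive_field",
    "conv_param_count",
    "serialized_megabytes",
]


@dataclass(frozen=True)
class ConvSpec:
    """Shape-level description of one convolution layer."""

    kernel: int
    dilation: int = 1
    stride: int = 1
    in_channels: int = 1
    out_channels: int = 1
    depthwise_separable: bool = False
    has_bias: bool = False

    def validate(self) -> "ConvSpec":
        for name in ("kernel", "dilation", "stride", "in_channels", "out_channels"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or value < 1:
                raise ValueError(f"ConvSpec.{name} must be a positive integer, got {value!r}")
        return self


@dataclass(frozen=True)
class LayerChain:
    """An ordered stack of convolutions, shallowest first."""

    layers: Sequence[ConvSpec]

    def validate(self) -> "LayerChain":
        if not self.layers:
            raise ValueError("LayerChain must contain at least one layer")
        for spec in self.layers:
            spec.validate()
        return self


@dataclass
class ParamReport:
    """Per-component parameter budget of a model."""

    per_component: Dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.per_component.values())

    @property
    def total_megabytes(self) -> float:
        return serialized_megabytes(self.total_count)

    def rows(self):
        """(component, count, MB) rows plus a total row, for the TSV report."""
        for name, count in self.per_component.items():
            yield name, count, serialized_megabytes(count)
        yield "total", self.total_count, self.total_megabytes


def effective_kernel_size(spec: ConvSpec) -> int:
    """Size of the dilated kernel: k + (k-1)(d-1)."""
    spec.validate()
    return spec.kernel + (spec.kernel - 1) * (spec.dilation - 1)


def cumulative_stride(chain: LayerChain, upto: int) -> int:
    """Product of the strides of layers 0..upto-1 (empty prefix -> 1)."""
    if upto < 0 or upto > len(chain.layers):
        raise IndexError(f"prefix length {upto} out of range for chain of {len(chain.layers)}")
    out = 1
    for spec in chain.layers[:upto]:
        spec.validate()
        out *= spec.stride
    return out


def receptive_field(chain: LayerChain) -> int:
    """Input extent seen by one unit of the chain's final output."""
    chain.validate()
    rf = 1
    for i, spec in enumerate(chain.layers):
        rf += (effective_kernel_size(spec) - 1) * cumulative_stride(chain, i)
    return rf


def conv_param_count(spec: ConvSpec) -> int:
    """Weights (+ biases) of one layer under the standard factorizations."""
    spec.validate()
    k, cin, cout = spec.kernel, spec.in_channels, spec.out_channels
    if spec.depthwise_separable:
        count = k * k * cin + cin * cout
        if spec.has_bias:
            count += cin + cout
    else:
        count = k * k * cin * cout
        if spec.has_bias:
            count += cout
    return count


def serialized_megabytes(count: int) -> float:
    """Decimal MB of a float32 buffer with ``count`` entries, 1-decimal."""
    if count < 0:
        raise ValueError("parameter count must be non-negative")
    return round(count * 4 / 1e6, 1)
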