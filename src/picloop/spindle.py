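"""Muscle-spindle feedback: length-dependent afferent drive to the dendrites.

Group Ia + II spindle input during an isometric length hold is modeled as a
tonically active excitatory conductance distributed uniformly over the soma
and every dendritic compartment within 1.4 mm of dendritic path.  The
density G_aff (μS/cm²) is a piecewise-linear function of muscle length
through three calibrated anchors (shortest, optimal, longest length), each
pinned by the effective synaptic current I_N it produces at the clamped
soma.  Motor-unit contraction does not modulate the spindle signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cable import CompartmentalModel
from .errors import ParameterError
from .morphology import NeuriteTree

AFFERENT_EXTENT_UM = 1400.0
AFFERENT_DELAY_MS = 10.0


@dataclass
class AfferentMap:
    """Placement of spindle synapses on a compartmental model."""

    comp_idx: np.ndarray          # compartments carrying afferent synapses
    total_area: float             # cm² of innervated membrane
    e_rev: float = 0.0            # mV
    delay: float = AFFERENT_DELAY_MS
    anchors: list = field(default_factory=list)  # [(X_m mm, G_aff μS/cm²)]


def gaff_of_length(x_m: float, anchors) -> float:
    """Afferent conductance density (μS/cm²) at muscle length ``x_m`` (mm).

    Piecewise-linear through the calibrated ``(X_m, G_aff)`` anchors
    (exact at the anchors).  ``x_m`` must lie within the anchor range.
    """
    anchors = sorted(anchors)
    xs = [x for x, _ in anchors]
    gs = [g for _, g in anchors]
    if not xs[0] <= x_m <= xs[-1]:
        raise ParameterError(f"X_m={x_m} outside calibrated range [{xs[0]}, {xs[-1]}]")
    return float(np.interp(x_m, xs, gs))


def place_afferents(tree: NeuriteTree, model: CompartmentalModel,
                    extent_um: float = AFFERENT_EXTENT_UM) -> AfferentMap:
    """Attach afferent synapse slots to the soma and all dendritic
    compartments with midpoint path length below ``extent_um``.

    Sets the model's unit-density conductance (``g_aff_unit``, μS at
    1 μS/cm²) so a scalar G_aff waveform scales the whole population
    synchronously and uniformly.
    """
    mask = (model.kind == 0) | ((model.kind == 1) & (model.path_um < extent_um))
    idx = np.nonzero(mask)[0]
    model.g_aff_unit = np.zeros(model.n)
    model.g_aff_unit[idx] = model.area[idx]  # μS/cm² × cm² → μS
    model.aff_idx = idx
    return AfferentMap(
        comp_idx=idx,
        total_area=float(model.area[idx].sum()),
        e_rev=model.spec.e_syn,
    )
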