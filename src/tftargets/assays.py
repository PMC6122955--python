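"""Closed-form bench-assay quantitation formulas.

Small helpers kept alongside the pipeline: qPCR relative quantitation,
ChIP-qPCR percent input, and the caliper tumor-volume estimate.
"""

from __future__ import annotations

import warnings


def relative_quantitation(delta_ct: float) -> float:
    """Fold change 2^-(Ct - Cc) from a normalized threshold-cycle difference.

    ``delta_ct`` is Ct(sample) - Ct(calibrator) after normalizing both to
    the endogenous control; 0 gives 1-fold, each extra cycle halves.
    """
    return 2.0 ** (-delta_ct)


def chip_percent_input(ct_input: float, ct_ip: float, input_fraction: float = 0.02) -> float:
    """ChIP-qPCR enrichment as percent of input chromatin.

    input_fraction x 2^(Ct_input - Ct_IP), returned as a percentage; equal
    threshold cycles return the input fraction itself (2% by default).
    ``input_fraction`` is the share of chromatin in the input aliquot
    (kit-dependent; 0.02 = a 2% input).
    """
    if ct_input <= 0 or ct_ip <= 0:
        raise ValueError("threshold cycles must be positive")
    return 100.0 * input_fraction * 2.0 ** (ct_input - ct_ip)


def tumor_volume(length: float, width: float) -> float:
    """Caliper volume estimate (length x width^2) / 2 in mm^3."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    if length < width:
        warnings.warn("length < width: arguments may be swapped", stacklevel=2)
    return length * width**2 / 2.0
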