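import numpy as np
import pytest

from csp_pocket.shift_io import Peak2D, ShiftRecord, ShiftTable


def make_table(entries, state="free", ratio=0.0):
    """entries: iterable of (resnum, restype, atom, ppm)."""
    return ShiftTable([ShiftRecord(*e) for e in entries], state_label=state,
                      molar_ratio=ratio)


@pytest.fixture
def free_bound_pair():
    """Two-residue free/bound tables with hand-chosen shift changes.

    Residue 1: ΔδH = 0.1, ΔδN = 0.5 (weighted Δδ = 0.1 exactly).
    Residue 2: ΔδH = 0.3, ΔδN = 0   (weighted Δδ = 0.212132...).
    """
    free = make_table([
        (1, "G", "H", 8.00), (1, "G", "N", 110.0),
        (2, "A", "H", 7.50), (2, "A", "N", 120.0),
    ])
    bound = make_table([
        (1, "G", "H", 8.10), (1, "G", "N", 110.5),
        (2, "A", "H", 7.80), (2, "A", "N", 120.0),
    ], state="bound", ratio=1.0)
    return free, bound


@pytest.fixture
def toy_peaks():
    return [
        Peak2D(8.00, 120.0, 1.0),
        Peak2D(8.50, 115.0, 2.0),
        Peak2D(7.20, 125.0, 0.5),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20171120)
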