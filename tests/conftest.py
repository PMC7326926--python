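import numpy as np
import pandas as pd
import pytest

from aquascore import (
    ImageSimParams,
    segment_and_quantify,
    simulate_core_image,
)


def small_params(seed: int = 0, **kwargs) -> ImageSimParams:
    """A compact core: fast to simulate and segment, still multi-cell."""
    defaults = dict(
        image_size_px=(160, 160),
        n_tumor_cells=8,
        n_t_cells=4,
        seed=seed,
    )
    defaults.update(kwargs)
    return ImageSimParams(**defaults)


@pytest.fixture(scope="session")
def default_core():
    """One default-sized core (50 tumor + 20 T cells) with truth."""
    return simulate_core_image(ImageSimParams(seed=42))


@pytest.fixture(scope="session")
def quantified_core(default_core):
    """The default core run through normalize/segment/quantify/gate."""
    stack, truth = default_core
    quant, wide = segment_and_quantify(stack)
    return stack, truth, quant, wide


def match_cells_to_truth(wide: pd.DataFrame, truth_cells: pd.DataFrame, tol: float):
    """Greedy nearest-centroid matching of detected cells to truth cells.

    Returns (n_matched, matched DataFrame with detected + truth columns).
    With well-separated synthetic cells the greedy match is unambiguous.
    """
    det = wide[["cell_id", "centroid_row", "centroid_col"]].to_numpy()
    tru = truth_cells[["label", "center_row", "center_col"]].to_numpy()
    used = set()
    rows = []
    for cid, r, c in det:
        d = np.hypot(tru[:, 1] - r, tru[:, 2] - c)
        order = np.argsort(d)
        for j in order:
            if d[j] > tol:
                break
            if j not in used:
                used.add(j)
                rows.append({"cell_id": int(cid), "truth_label": int(tru[j, 0]),
                             "dist": float(d[j])})
                break
    return len(rows), pd.DataFrame(rows)
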