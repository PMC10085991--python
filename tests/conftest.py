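import numpy as np
import pandas as pd
import pytest

from ctdyn.synthetic import NmrGroundTruth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_peaklist(residues, dh, dn, intensity=None):
    return pd.DataFrame(
        {
            "residue": np.asarray(residues, int),
            "dH_ppm": np.asarray(dh, float),
            "dN_ppm": np.asarray(dn, float),
            "intensity": (
                np.ones(len(residues)) if intensity is None else np.asarray(intensity, float)
            ),
        }
    )


@pytest.fixture
def nmr_truth():
    """Small ground truth over CT residues with one proline-like gap."""
    residues = tuple(range(347, 357))
    n = len(residues)
    return NmrGroundTruth(
        residues=residues,
        base_dh=tuple(8.0 + 0.01 * i for i in range(n)),
        base_dn=tuple(115.0 + 0.5 * i for i in range(n)),
        delta_dh=tuple(0.02 if 350 <= r <= 353 else 0.0 for r in residues),
        delta_dn=tuple(0.10 if 350 <= r <= 353 else 0.0 for r in residues),
        intensity_scaling=tuple(1.5 if 350 <= r <= 353 else 1.0 for r in residues),
        missing_residues=frozenset({352}),
    )
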