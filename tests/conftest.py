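import numpy as np
import pandas as pd
import pytest

from tsetscan import ExpressionDataset, fuse_platforms


def _det(lib, panel, subunit, validated=True):
    return {
        "library_id": lib,
        "panel": panel,
        "subunit": subunit,
        "detected": True,
        "validated": validated,
    }


@pytest.fixture
def census_fixture():
    """Hand-built 12-library, 3-group census substrate with a frozen tally.

    Group A: 3 of 4 libraries pass the AP1 gate; a1 carries a complete
    complex; a3 has every target subunit but fails the gate.
    Group B: 3 of 4 pass; only TSPOON/TCUP are ever detected.
    Group C: nobody passes (c1's two AP1 hits are unvalidated).
    """
    rows = []
    manifest = pd.DataFrame(
        [
            {
                "library_id": f"{g}{i}",
                "species": f"sp_{g}{i}",
                "taxon_group": {"a": "GroupA", "b": "GroupB", "c": "GroupC"}[g],
                "lineage": "Eukaryota;Algae",
                "data_type": "genome",
            }
            for g in "abc"
            for i in range(1, 5)
        ]
    )
    tset_all = ["TSPOON", "TCUP", "TPLATE", "TSAUCER", "TTRAY1", "TTRAY2"]
    rows += [_det("a1", "AP1", s) for s in
             ["AP1-beta", "AP1-gamma", "AP1-mu", "AP1-sigma"]]
    rows += [_det("a1", "TSET", s) for s in tset_all]
    rows += [_det("a2", "AP1", s) for s in ["AP1-beta", "AP1-mu"]]
    rows += [_det("a2", "TSET", s) for s in ["TPLATE", "TSPOON"]]
    rows += [_det("a3", "AP1", "AP1-beta")]
    rows += [_det("a3", "TSET", s) for s in tset_all]
    rows += [_det("a4", "AP1", s) for s in ["AP1-beta", "AP1-gamma"]]
    rows += [_det("a4", "TSET", "TPLATE")]

    rows += [_det("b1", "AP1", s) for s in ["AP1-beta", "AP1-sigma"]]
    rows += [_det("b2", "AP1", s) for s in ["AP1-gamma", "AP1-mu"]]
    rows += [_det("b2", "TSET", "TCUP")]
    rows += [_det("b3", "AP1", s) for s in
             ["AP1-beta", "AP1-gamma", "AP1-mu", "AP1-sigma"]]
    rows += [_det("b3", "TSET", s) for s in ["TSPOON", "TCUP"]]
    # b4: no detections at all

    rows += [_det("c1", "AP1", s, validated=False)
             for s in ["AP1-beta", "AP1-gamma"]]
    rows += [_det("c2", "AP1", "AP1-mu")]
    rows += [_det("c2", "TSET", "TPLATE")]
    # c3, c4: nothing

    detections = pd.DataFrame(rows)
    hand_tally = {
        "GroupA": {
            "n_ap1_positive": 3,
            "counts": {"TSPOON": 2, "TCUP": 1, "TPLATE": 3,
                       "TSAUCER": 1, "TTRAY1": 1, "TTRAY2": 1},
            "sectors": {"TSPOON": "majority", "TCUP": "single",
                        "TPLATE": "majority", "TSAUCER": "single",
                        "TTRAY1": "single", "TTRAY2": "single"},
            "n_complete": 1,
        },
        "GroupB": {
            "n_ap1_positive": 3,
            "counts": {"TSPOON": 1, "TCUP": 2, "TPLATE": 0,
                       "TSAUCER": 0, "TTRAY1": 0, "TTRAY2": 0},
            "sectors": {"TSPOON": "single", "TCUP": "majority",
                        "TPLATE": "absent", "TSAUCER": "absent",
                        "TTRAY1": "absent", "TTRAY2": "absent"},
            "n_complete": 0,
        },
        "GroupC": {"n_ap1_positive": 0, "n_complete": 0},
    }
    return manifest, detections, hand_tally


@pytest.fixture
def tiny_ranked():
    """Two-platform fused matrix, 4 genes, 3+3 samples, one masked value and
    one gene absent from platform B."""
    a = ExpressionDataset(
        platform="rnaseq_abundance",
        values=pd.DataFrame(
            {
                "a1": [5.0, 1.0, 3.0, 2.0],
                "a2": [1.0, 2.0, 3.0, 4.0],
                "a3": [2.0, np.nan, 1.0, 3.0],
            },
            index=["g1", "g2", "g3", "g4"],
        ),
    )
    b = ExpressionDataset(
        platform="microarray_foldchange",
        values=pd.DataFrame(
            {
                "b1": [0.5, -0.5, 1.5],
                "b2": [2.0, 2.0, 1.0],
                "b3": [-1.0, 0.0, 1.0],
            },
            index=["g1", "g2", "g3"],  # g4 not evaluated on this platform
        ),
    )
    return fuse_platforms([a, b])
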