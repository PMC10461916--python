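import numpy as np
import pytest

from folatedms import (
    SelectionSpec,
    default_model_params,
    generate_truth_table,
    infer_growth_rates,
    simulate_selection_counts,
)


@pytest.fixture(scope="session")
def params():
    return default_model_params()


@pytest.fixture(scope="session")
def small_selection(params):
    """A small selection experiment shared across modules: truth, counts
    and inferred growth records in the three DMS backgrounds."""
    truth = generate_truth_table(n_positions=16, params=params, seed=2)
    spec = SelectionSpec(seed=11)
    bulk = {r: spec.bulk_rate for r in (1, 2, 3)}
    records = {}
    for bg in ("WT", "Q33S", "R166Q"):
        table = simulate_selection_counts(truth, spec, background=bg)
        records[bg] = infer_growth_rates(table, bulk, background=bg)
    return {"truth": truth, "spec": spec, "records": records}


@pytest.fixture()
def toy_pdb(tmp_path):
    """Minimal PDB: a folate ligand C6 atom at the origin plus two residues."""
    lines = [
        "ATOM      1  N   ALA A   1       3.000   4.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A   1       6.000   8.000   0.000  1.00  0.00           C",
        "ATOM      3  N   GLY A   2       0.000   0.000   9.000  1.00  0.00           N",
        "HETATM    4  C6  FOL A 200       0.000   0.000   0.000  1.00  0.00           C",
        "END",
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
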