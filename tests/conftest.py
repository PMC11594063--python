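import logging

import numpy as np
import pytest

import surfdelta as sd
from surfdelta.synth import write_ensemble_pdb

logging.getLogger("surfdelta").setLevel(logging.WARNING)
for name in ("surfdelta.structure_io", "surfdelta.surface", "surfdelta.region",
             "surfdelta.resample_stats", "surfdelta.ensemble", "surfdelta.pipeline"):
    logging.getLogger(name).setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def toy_pair():
    """A 20-residue toy protein and a -2e charge-flip mutant at residue 7."""
    wt, _ = sd.make_toy_protein(sd.ToySpec(n_residues=20, seed=2))
    site = sd.SiteSpec(chain_id="A", residue_number=7, wt_aa="K", mut_aa="D")
    mut = sd.make_mutant(wt, site, delta_charge=-2.0)
    return wt, mut, site


@pytest.fixture(scope="session")
def toy_files(toy_pair, tmp_path_factory):
    """The toy pair on disk: PQR files plus 3-frame rigid ensembles."""
    wt, mut, site = toy_pair
    d = tmp_path_factory.mktemp("toy")
    sd.write_pqr(wt, d / "wt.pqr")
    sd.write_pqr(mut, d / "mut.pqr")
    for tag, model in (("wt", wt), ("mut", mut)):
        ens = sd.make_wobble_ensemble(model, n_frames=3, amplitude=0.0, seed=0)
        write_ensemble_pdb(ens, d / f"{tag}.pdb")
    return d, site


@pytest.fixture(scope="session")
def single_atom_model():
    return sd.structure_io.model_from_atoms([dict(
        serial=1, name="CA", res_name="GLY", chain_id="A", res_id=1,
        coord=(0.03, 0.11, -0.07), charge=0.0, radius=1.6,
    )])


@pytest.fixture(scope="session")
def labeled_toy_mesh(toy_pair):
    """Toy WT surface with residue labels and screened-Coulomb potential."""
    wt, _, _ = toy_pair
    mesh = sd.compute_ses(wt)
    mesh = sd.assign_vertices_to_residues(mesh, wt)
    phi = sd.screened_coulomb_potential(wt, mesh.vertices)
    return mesh.with_potential(phi)
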