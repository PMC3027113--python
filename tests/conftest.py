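import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from psnvar import SimConfig, gen_dataset
from psnvar.structure import ResidueNode, StructureModel

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def model_from_centroids(centroids, aas=None, protein_id="toy") -> StructureModel:
    """StructureModel built directly from centroid coordinates (test shortcut)."""
    centroids = np.asarray(centroids, dtype=float)
    if aas is None:
        aas = ["A"] * len(centroids)
    residues = [
        ResidueNode(chain_id="A", seq_index=i + 1, resnum=str(i + 1), aa=aa,
                    centroid=c)
        for i, (aa, c) in enumerate(zip(aas, centroids))
    ]
    return StructureModel(protein_id=protein_id, chain_id="A", residues=residues)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small but complete synthetic study: 4 proteins, 120 variants."""
    out_dir = tmp_path_factory.mktemp("smallsim")
    cfg = SimConfig(n_proteins=4, residues_range=(30, 45), n_saps=120, seed=11)
    return cfg, gen_dataset(cfg, out_dir)
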