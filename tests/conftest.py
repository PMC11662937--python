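import numpy as np
import pytest

from acetrna import synthetic_data as sd
from acetrna import trna_model as tm


@pytest.fixture(scope="session")
def sim_cfg():
    return sd.SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_genome_files(sim_cfg, tmp_path_factory):
    """A simulated genome written to disk: (paths dict, SimulatedGenome)."""
    genome = sd.sim_genome(sim_cfg)
    outdir = tmp_path_factory.mktemp("genome")
    paths = genome.write(outdir)
    return paths, genome


@pytest.fixture(scope="session")
def sim_gene_records(sim_genome_files):
    paths, _ = sim_genome_files
    return tm.parse_trna_genes(paths["bed"], paths["fasta"],
                               paths["structures"])


@pytest.fixture()
def canonical_trna():
    """A deterministic canonical tRNA body + structure (Arg/TCT anticodon)."""
    rng = np.random.default_rng(7)
    return sd.make_canonical_trna(rng, anticodon="TCT")


def write_fasta(path, chroms):
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n{seq}\n")
    return path
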