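import numpy as np
import pytest

from clonalpop import synthdata as sd


@pytest.fixture(scope="session")
def small_spec():
    return sd.PopulationSpec(
        n_populations=2,
        samples_per_population=3,
        n_sites=2000,
        private_snvs_per_population=20,
        private_snvs_per_sample=5,
        shared_snvs_all=50,
        reference_het_fraction=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_spec):
    """Reference profile + truth matrix + lineage for the small cohort."""
    ref = sd.generate_reference_profile(
        small_spec.n_sites, small_spec.reference_het_fraction, seed=small_spec.seed
    )
    truth, lineage = sd.generate_clonal_genotypes(small_spec, ref)
    return ref, truth, lineage


@pytest.fixture(scope="session")
def clean_vcf(small_world, tmp_path_factory):
    """Error-free, saturating-depth VCF of the small cohort."""
    ref, truth, _ = small_world
    path = tmp_path_factory.mktemp("vcf") / "cohort.vcf"
    model = sd.ReadModel(mean_depth=80.0, depth_dispersion=0.0, error_rate=0.0)
    sd.emit_vcf(truth, ref, model, path, seed=7)
    return path


def truth_site_index(truth):
    """Map (contig, position) -> column index of the truth matrix."""
    return {
        (str(c), int(p)): i
        for i, (c, p) in enumerate(zip(truth.contigs, truth.positions))
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
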