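import pytest

from neodepletion import BindingWindow, HlaGenotype, ProteinRecord
from neodepletion.simulate import SimulationConfig, generate_cohort, write_cohort


@pytest.fixture
def protein20():
    # length-20 protein; sequence is arbitrary but fixed
    return ProteinRecord.make("P1", "G1", "ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture
def tiny_sim_config():
    """Small, fast cohort: 5 proteins, 10 patients."""
    return SimulationConfig(
        seed=11,
        n_proteins=5,
        protein_length=(60, 120),
        n_patients=10,
        mutation_rate=0.02,
        synonymous_rate=0.02,
    )


@pytest.fixture
def tiny_cohort(tiny_sim_config):
    return generate_cohort(tiny_sim_config)


@pytest.fixture
def tiny_cohort_dir(tmp_path, tiny_cohort):
    outdir = tmp_path / "cohort"
    write_cohort(tiny_cohort, outdir)
    return outdir


def random_display_instance(rng, peptide_length=9):
    """A random small (protein, windows-by-allele, genotype) instance.

    Used by the brute-force mask oracles in the display tests.
    """
    from neodepletion.types import AMINO_ACIDS, DEFAULT_ALLELE_PANEL

    L = int(rng.integers(peptide_length, 60))
    seq = "".join(rng.choice(list(AMINO_ACIDS), L))
    prot = ProteinRecord.make(f"P{rng.integers(1e6)}", "G", seq)
    panel = DEFAULT_ALLELE_PANEL
    windows_by_allele = {}
    for allele in rng.choice(panel, size=rng.integers(1, 6), replace=False):
        n_w = int(rng.integers(0, 4))
        ws = [
            BindingWindow(
                prot.protein_id, allele,
                int(rng.integers(1, L - peptide_length + 2)),
                float(rng.uniform(1, 50)),
            )
            for _ in range(n_w)
        ]
        windows_by_allele[str(allele)] = ws
    # genotype: two alleles per locus, drawn from panel + an external allele
    copies: dict[str, int] = {}
    for locus in ("A", "B"):
        pool = [a for a in panel if a.startswith(locus)] + [f"{locus}*9901"]
        for a in rng.choice(pool, size=2, replace=True):
            copies[str(a)] = copies.get(str(a), 0) + 1
    genotype = HlaGenotype("S1", copies)
    return prot, windows_by_allele, genotype
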