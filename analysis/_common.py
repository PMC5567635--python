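"""Shared study configuration for the numbered analysis scripts.

One desk-scale synthetic study (seed 17) threads through every script:
200 homoeolog pairs plus 20 unpaired genes per subgenome, 17% subgenome
divergence, two accessions x three replicates of 60,000 paired-end
fragments, 30 truly differentially expressed genes of which 8 pairs are
coordinated, 2x AT dominance, and accession SNPs with a shared core and a
five-member reference panel.
"""

from pathlib import Path

from homeopipe import synthsim

STUDY_SEED = 17
RESULTS = Path(__file__).resolve().parent.parent / "results"
# raw study data (FASTQs etc.) is bulky and regenerable: keep it out of results/
STUDY_DIR = Path(__file__).resolve().parent.parent / "scratch" / "study"


def study_config() -> synthsim.SimulationConfig:
    return synthsim.SimulationConfig.desk_scale(
        seed=STUDY_SEED,
        n_pairs=200,
        n_unpaired_per_subgenome=20,
        reads_per_sample=60_000,
        n_de_genes=30,
        n_coordinated_pairs=8,
    )


def load_truth() -> synthsim.TruthSet:
    """Regenerate the study truth deterministically (cheap, seconds)."""
    return synthsim.simulate_study(study_config())
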