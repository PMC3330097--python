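"""Shared paths and loaders for the numbered analysis scripts.

`01_simulate_experiment.py` writes the synthetic inputs under
results/data/; later scripts read them back through the package's I/O layer
and write their tables under results/tables/.
"""

from pathlib import Path

from fieldexpr import core_data

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
TABLES = ROOT / "results" / "tables"

SEED = 1


def load_inputs():
    matrix = core_data.read_expression(DATA / "expression.tsv")
    flags = core_data.read_flags(DATA / "flags.tsv")
    samples = core_data.read_samples(DATA / "samples.tsv")
    env = core_data.read_environment(DATA / "environment.csv")
    pheno = core_data.read_phenotypes(DATA / "phenotypes.tsv")
    return matrix, flags, samples, env, pheno


def ensure_dirs():
    DATA.mkdir(parents=True, exist_ok=True)
    TABLES.mkdir(parents=True, exist_ok=True)
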