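"""Generate the synthetic field experiment all later scripts analyse.

Two accessions, 6+8 vegetative and 2+2 flowering timepoints sampled every
3 days, triplicate arrays with one late replicate lost (53 arrays), spring
weather (mean low ~8.7 C, mean high ~23.7 C, rain on ~8/30 days), planted
accession/flowering/environment effects, five co-expressed clusters, and a
third of genes below the detection floor. Writes the data tables plus the
planted truth and the stress gene-set collection under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import DATA, SEED, ensure_dirs

from fieldexpr import core_data, synthgen


def main() -> None:
    ensure_dirs()
    cfg = synthgen.SimulationConfig(n_genes=2000, seed=SEED)
    exp = synthgen.simulate_experiment(cfg)
    sets, categories = synthgen.synthetic_stress_sets(exp.truth, seed=SEED)

    core_data.write_expression(exp.matrix, DATA / "expression.tsv")
    core_data.write_flags(exp.flags, DATA / "flags.tsv")
    core_data.write_samples(exp.samples, DATA / "samples.tsv")
    core_data.write_environment(exp.environment, DATA / "environment.csv")
    core_data.write_phenotypes(exp.phenotypes, DATA / "phenotypes.tsv")
    core_data.write_gene_sets(sets, DATA / "stress_sets.gmt")
    exp.truth.effects.to_csv(DATA / "truth.tsv", sep="\t")
    with open(DATA / "set_categories.tsv", "w") as fh:
        fh.write("set\tcategory\n")
        for name, cat in categories.items():
            fh.write(f"{name}\t{cat}\n")

    n, m = exp.matrix.shape
    print(f"simulated {n} genes x {m} arrays "
          f"({len(exp.samples.data.groupby(['accession', 'day']))} samples)")
    print("realized variance fractions:",
          {k: round(v, 3) for k, v in exp.truth.realized_fractions.items()})
    env = exp.environment.data
    rainy = (env["precipitation"] > 0).sum()
    print(f"weather: mean tmin {env['tmin'].mean():.1f} C, "
          f"mean tmax {env['tmax'].mean():.1f} C, rain on {rainy}/{len(env)} days")


if __name__ == "__main__":
    main()
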