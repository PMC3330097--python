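"""PVCA of the full matrix: what drives transcriptional variance?

First the design model (accession + flowering status + interaction), then,
within each accession, the environmental/developmental model
(age + flowering status + tmin + tmax + precipitation), continuous
covariates entering as tertile-binned random effects.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import TABLES, ensure_dirs, load_inputs

from fieldexpr import core_data, pvca


def main() -> None:
    ensure_dirs()
    matrix, _, samples, env, pheno = load_inputs()
    design = core_data.join_design(samples, env, pheno)

    decomp = pvca.pvca(matrix, design)
    decomp.as_series().to_csv(TABLES / "pvca_global.tsv", sep="\t", header=True)
    print("global variance decomposition:")
    for factor, share in decomp.proportions.items():
        print(f"  {factor:35s} {100 * share:5.1f}%")

    env_decomp = pvca.pvca_environmental(matrix, design, by_accession=True)
    rows = [{"accession": acc, "factor": f, "proportion": v}
            for acc, d in env_decomp.items() for f, v in d.proportions.items()]
    pd.DataFrame(rows).to_csv(TABLES / "pvca_environmental.tsv", sep="\t", index=False)
    for acc, d in env_decomp.items():
        top = sorted(((v, k) for k, v in d.proportions.items() if k != "residual"),
                     reverse=True)
        print(f"{acc}: flowering {100 * d.proportions['flowering_status']:.0f}%, "
              f"precipitation {100 * d.proportions.get('precipitation', 0.0):.0f}%, "
              f"top factor {top[0][1]}")


if __name__ == "__main__":
    main()
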