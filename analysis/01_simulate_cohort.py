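"""Generate the synthetic staged MI-like cohort and its regulatory inputs.

Emulated design: 14 stable controls vs 28 cases sampled at three stages
(acute / subacute / chronic), 2000 genes with 10% planted DE whose effect
decays across stages, 10 planted miRNA-TF feed-forward loops among 500 decoy
edges, 50 subpathway gene sets (5 with planted enrichment), and a planted
two-gene diagnostic signal.
"""

import json

from common import WORKDIR, parse_args
from ffl_dynamics.synthetic import SimConfig, write_inputs


def main() -> None:
    args = parse_args(__doc__)
    cfg = SimConfig(seed=args.seed)
    paths = write_inputs(WORKDIR / "inputs", cfg)
    truth = json.loads(paths["ground_truth"].read_text())
    print(f"wrote {len(paths)} input files under {WORKDIR / 'inputs'}")
    print(f"planted DE genes per stage: {len(truth['de_genes_per_stage']['1'])}")
    print(f"planted feed-forward loops: {len(truth['planted_ffls'])}")
    print(f"planted biomarker panel:    {truth['biomarker_genes']}")


if __name__ == "__main__":
    main()
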