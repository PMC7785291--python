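"""Score the simulated pulldown: fold-change, Z, p, FDR per orthogroup.

Reads the tables written by 01_simulate_pulldowns.py (running that step
first if needed), scores every orthogroup against the pooled GFP controls,
and writes the ranked results plus the bait–prey edge list (the numbers
behind a spoke diagram) under results/.
"""

import importlib
import pathlib

from dynapquant.enrichment import score_experiment
from dynapquant.tables_io import read_pairing, read_psm_table, write_results

ROOT = pathlib.Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"


def run() -> None:
    if not (SIM / "psm.tsv").exists():
        importlib.import_module("01_simulate_pulldowns").run()
    table = read_psm_table(SIM / "psm.tsv")
    spec = read_pairing(SIM / "pairing.tsv")
    idmap = {p: p for p in table["protein_id"]}  # table is already group-level
    res = score_experiment(table, idmap, spec, "bait", "g000")
    write_results(res, ROOT / "results" / "enrichment.tsv",
                  ROOT / "results" / "edges.tsv")
    n_sig = int(res["significant"].sum())
    print(f"universe n={len(res)}, significant at z>=1.645: {n_sig}")
    print("top 5 hits:")
    cols = ["group_id", "psm_expt", "psm_ctrl", "log2_fc", "z", "fdr", "is_bait"]
    print(res[cols].head(5).to_string(index=False, float_format="%.3g"))
    bait_rank = res.index[res["is_bait"]][0] + 1
    print(f"the bait ranks #{bait_rank} — the positive control of the screen")


if __name__ == "__main__":
    run()
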