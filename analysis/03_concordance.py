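#!/usr/bin/env python
"""Concordance between the called lifespan set and the planted partner set.

The partner set emulates an external aging/lifespan signature planted at a
concordance odds ratio of 3 against the truth genes; significance is the
two-sided binomial overlap test.
"""

from pathlib import Path

import pandas as pd

from lifecon.pipeline import load_config, run_concord, stage_seed

HERE = Path(__file__).parent


def main() -> None:
    cfg = load_config(HERE / "study.toml")
    out_dir = Path(cfg["out_dir"])
    run_concord(cfg.get("concord", {}), out_dir, stage_seed(cfg["seed"], "concord"))
    row = pd.read_csv(out_dir / "concord.tsv", sep="\t", comment="#").iloc[0]
    print(f"universe {int(row.n_universe)} genes; query set {int(row.n_a)} genes")
    print(f"concordant observed {int(row.concordant)} vs expected "
          f"{row.expected_concordant:.1f}  OR={row.or_concordant:.2f}  "
          f"p={row.p_concordant:.2e}")
    print(f"discordant observed {int(row.discordant)} vs expected "
          f"{row.expected_discordant:.1f}  OR={row.or_discordant:.2f}  "
          f"p={row.p_discordant:.2e}")


if __name__ == "__main__":
    main()
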