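#!/usr/bin/env python
"""Fisher-exact enrichment of the called gene set.

Tests the merged call set against the synthetic annotation library (the
planted term plus random decoys) over the investigated-gene background.
"""

from pathlib import Path

import pandas as pd

from lifecon.pipeline import load_config, run_enrich, stage_seed

HERE = Path(__file__).parent


def main() -> None:
    cfg = load_config(HERE / "study.toml")
    out_dir = Path(cfg["out_dir"])
    run_enrich(cfg.get("enrich", {}), out_dir, stage_seed(cfg["seed"], "enrich"))
    df = pd.read_csv(out_dir / "enrich.tsv", sep="\t", comment="#")
    print("top terms:")
    print(df.head(5).to_string(index=False))
    print(f"{int(df.significant.sum())} term(s) significant at FDR < 0.05")


if __name__ == "__main__":
    main()
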