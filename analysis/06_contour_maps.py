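#!/usr/bin/env python
"""Export STDEV*COEFF contour fields for every model channel.

Loads the field matrix (run 03 first), refits both models, computes the
sigma*coefficient field per channel with 80%/20% contribution contour
levels, writes OpenDX grids to scratch/contours/ and the level summary to
results/contour_levels.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from trpa1_qsar import compounds as cmpd
from trpa1_qsar import fields as f
from trpa1_qsar import gridio
from trpa1_qsar.pipeline import RunConfig, _fit_one_model

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    fm = f.load_field_matrix(ROOT / "scratch" / "field_matrix")
    records = cmpd.load_compound_table()
    table = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "pec50_actual": [r.pec50_actual for r in records],
            "subset": [r.subset for r in records],
        }
    )
    cfg = RunConfig()
    dx_dir = ROOT / "scratch" / "contours"
    dx_dir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for name, channels in (("comfa", f.COMFA_CHANNELS), ("comsia", f.COMSIA_CHANNELS)):
        result = _fit_one_model(name.upper(), channels, fm, table, cfg)
        for short, field in result.contours.items():
            gridio.write_dx(
                dx_dir / f"{name}_{short}.dx", field.values, fm.grid,
                metadata={"channel": field.channel,
                          "favored_level": field.favored_level,
                          "disfavored_level": field.disfavored_level},
            )
            summary[f"{name}_{short}"] = {
                "favored_level": field.favored_level,
                "disfavored_level": field.disfavored_level,
                "n_nonzero": int((field.values != 0).sum()),
            }
            print(f"{name}_{short:15s} favored>={field.favored_level:8.4f} "
                  f"disfavored<={field.disfavored_level:8.4f} "
                  f"({summary[f'{name}_{short}']['n_nonzero']} active points)")
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "contour_levels.json").write_text(json.dumps(summary, indent=1))
    print("\nDX grids -> scratch/contours/ (loadable in PyMOL/VMD/Chimera); "
          "channels whose columns all fall below the variance filter export "
          "as all-zero fields.")


if __name__ == "__main__":
    main()
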