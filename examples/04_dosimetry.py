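"""Compare sensitiser in vitro test concentrations with in vivo estimates.

Loads the packaged concentration table for the five respiratory
sensitisers (PA, GLUT, TDI, MA, TMA) and prints every in vitro / in vivo
fold ratio with its order of magnitude.  Chemicals without a quantitative
in vivo estimate are flagged with the reason.
"""

from aoplink.dosimetry import (
    compare_table,
    format_fold,
    load_concentration_table,
    load_notes,
)

records = load_concentration_table()
comparisons = compare_table(records, notes=load_notes())

for c in comparisons:
    if c.fold is None:
        print(f"{c.chemical}: no fold ratio — {c.reason}")
        continue
    print(
        f"{c.chemical}: {c.in_vitro.value:g} uM ({c.in_vitro.context.split('_')[-1]}) "
        f"vs {c.in_vivo.value:g} uM ({c.in_vivo.medium}, {c.in_vivo.scenario}) "
        f"-> {format_fold(c.fold)}-fold, {c.orders_of_magnitude:.1f} orders of magnitude"
    )
# Folds far above 1 mean cells were dosed well beyond internal
# concentrations expected from realistic occupational exposure, so
# enrichment observed in vitro needs cautious in vivo interpretation.
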