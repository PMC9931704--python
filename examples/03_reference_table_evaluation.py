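"""Fold-error evaluation of the packaged reference PK-parameter table.

Loads the packaged table of observed and predicted AUC, C_max and CL/F for the
14 reference children, recomputes the predicted/observed fold errors, and
prints the aggregate statistics: mean ratio with 95% CI, average fold error
(geometric mean) and two-fold counting.
"""

from captoped import afe, fold_error, load_fixture, mean_ratio_ci, twofold_check
from captoped.nca import cl_f
from captoped.synthdata import quarantined_cells

table = load_fixture("table2")
quarantine = quarantined_cells()

print("dose/AUC -> CL/F identity (2 dp), skipping quarantined cells:")
bad = 0
for row in table.to_dict("records"):
    for col in ("obs", "pred"):
        if (row["id"], f"clf_{col}") in quarantine:
            continue
        bad += round(cl_f(row["dose"], row[f"auc_{col}"]), 2) != row[f"clf_{col}"]
print(f"  {bad} inconsistencies outside the {len(quarantine)} quarantined cells")

for param, label in (("auc", "AUC_0-t"), ("cmax", "C_max")):
    ratios = [
        fold_error(r[f"{param}_obs"], r[f"{param}_pred"]) for r in table.to_dict("records")
    ]
    mean, (lo, hi) = mean_ratio_ci(ratios)
    flags, frac = twofold_check(ratios)
    print(
        f"{label}: mean ratio {mean:.2f} (95% CI {lo:.2f}-{hi:.2f}), "
        f"AFE {afe(ratios):.2f}, {int(flags.sum())}/{len(ratios)} within two-fold"
    )
print("\nAFE near 1 means little net bias; ratios within [0.5, 2] are the")
print("conventional acceptance band for PBPK predictions.")
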