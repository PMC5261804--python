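"""Patient survival stratified by PPI presence.

Patients lose a PPI when a partner gene carries a truncating mutation or a
homozygous deletion. The synthetic cohort plants a 3x hazard ratio on one
PPI: patients who retain it fare worse. The screen computes a log-rank p
per PPI, adjusts with Benjamini-Yekutieli, and gates hits on the KS rank
statistic (the PPI must also be consistently essential in the cell lines).
"""

from ppiscore.metrics import ks_by_group, ppi_key
from ppiscore.pipeline import build_matrix
from ppiscore.screens import patient_status_records, qq_expected, survival_screen
from ppiscore.simulate import SimulationConfig, generate_all, planted_choices

cfg = SimulationConfig(seed=11)
sp, shrna, contexts, drug, mutations, clinical = generate_all(cfg)
matrix = build_matrix(sp, shrna, contexts={c.cell_line: c for c in contexts})
_, planted = planted_choices(cfg, sp)
planted_key = ppi_key(*planted)

ks = ks_by_group(matrix, matrix.columns)
status = patient_status_records(mutations, clinical, list(matrix.index))
table = survival_screen(status, ks.to_dict(), ks_threshold=0.5, alpha=0.05)

ev = table[table["evaluable"]]
print(f"screened {len(table)} PPIs; {len(ev)} evaluable (both groups occupied)")
print(f"planted PPI {planted_key}: log-rank p = {table.loc[planted_key, 'p']:.2e}, "
      f"BY-adjusted = {table.loc[planted_key, 'p_by']:.2e}, "
      f"KS = {table.loc[planted_key, 'ks']:.2f}")
hits = table[table["passes"]]
print(f"{len(hits)} PPI(s) pass both gates (nominal p < 0.05 and KS > 0.5):")
for ppi, row in hits.iterrows():
    print(f"  {ppi}: p={row['p']:.2e}  p_BY={row['p_by']:.2e}  ks={row['ks']:.2f}")

qq = qq_expected(ev["p"].to_numpy())
excess = (qq["neglog10_observed"] > qq["neglog10_expected"]).mean()
print(f"\nQQ check: {excess:.0%} of observed p-values are more extreme than")
print("their uniform expectation — background PPIs sit near the diagonal,")
print("the planted PPI far above it.")
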