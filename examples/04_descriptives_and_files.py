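"""Round-trip through the table files plus descriptive outputs.

Writes a synthetic database as dollar-delimited FAERS-style tables,
re-reads and deduplicates them, prints the cohort characteristics table
and annual report counts, and writes a full report bundle.
"""

import tempfile
from pathlib import Path

import pvsignal as pv

config = pv.SyntheticConfig(n_cases=5_000, seed=4, p_duplicate=0.1)
workdir = Path(tempfile.mkdtemp())
paths = pv.write_faers_tables(pv.generate(config), workdir / "tables")
print(f"wrote tables to {workdir / 'tables'}")

tables = pv.read_faers_tables(paths)
retained = pv.deduplicate(tables.demo)
print(f"{len(tables.demo)} DEMO rows -> {len(retained)} after deduplication "
      "(older shadow copies removed)")

cases = pv.assemble_cases(tables, retained)
exposed, background = pv.filter_primary_suspect(cases, config.target_drug)

table = pv.describe_cohort(exposed)
sex = table[table["characteristic"] == "sex"]
print("\nExposed-cohort sex distribution (count, percent):")
print(sex[["category", "count", "percent"]].to_string(index=False))

years = pv.annual_counts(exposed)
first, last = min(years), max(years)
print(f"\nannual counts span {first}-{last}; total "
      f"{sum(years.values())} = exposed cohort size {len(exposed)}")

results = pv.screen(exposed, background)
bundle = pv.write_report_bundle(
    workdir / "bundle", exposed, results,
    config_echo={"n_cases": config.n_cases}, seed=config.seed,
)
print(f"\nreport bundle in {bundle}: "
      f"{', '.join(sorted(p.name for p in bundle.iterdir()))}")
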