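# iplome

Informatics for environmental **intact polar lipidomics** (IPL): the
membrane lipids of living microbial communities, measured by untargeted
HILIC-Orbitrap LC-MS in settings — serpentinite-hosted aquifers, hot
springs, the oligotrophic ocean — where the lipid repertoire runs far
beyond what common lipidomics databases cover (ether lipids, archaeol
and GDGTs, ornithine and betaine aminolipids, glycosphingolipids,
ladderanes).

The package is for geobiologists and organic geochemists who need to go
from aligned LC-MS feature tables and MS2 spectra to annotated,
semi-quantified lipidomes and the derived geochemical statistics. It
provides:

- **Combinatorial theoretical databases** — components (headgroup +
  backbone base formulas) iterated over chain states (2-30 C and 0-6
  double bonds per chain under a 3n+2 spacing rule, up to 3
  hydroxylations per species) across 8 backbone linkage types, plus
  full-structure cores (archaeol, iso/branched GDGTs and GDDs,
  ladderanes) expanded over modification grids, ionized as
  [M+H]+ / [M+NH4]+ / [M-H]- / [M+HCOO]-.
- **Annotation** — ppm-windowed MS1 matching; positive-mode MS2
  diagnostics for headgroups, negative-mode fatty-acid anions for chain
  confirmation; deterministic structural-isomer resolution (direct
  confirmation, 15-s neighbor linkage transfer, no-hydroxylation
  default), with provenance on every assignment.
- **Semi-quantification** — 10x blank filtering, internal-standard
  (d9-DGTS) matrix correction, dilution-series response factors with
  headgroup-similarity class assignment, volume normalization to ng/L.
- **Lipidome statistics** — mole fractions; abundance-weighted
  structural properties `Xi = sum(Xi_i x_i) / sum(n_i x_i)`; carbon
  oxidation state `Zc = (Z + 2o + 3n - 5p - 4s - h)/c` of whole lipids
  and their headgroup/backbone/chains partitions; Pearson/Bonferroni
  taxa-lipid correlation; Hellinger and Gower preprocessing for
  constrained ordination.
- **A synthetic-data generator** with known ground truth (noise on m/z,
  areas and retention time; blanks; dilution series), so the whole
  pipeline is testable without instrument data.

Zc tracks how reduced a biomolecule's carbon is (CH4 = -4, CO2 = +4);
abundance-weighted Zc of lipid parts is a proxy for the redox
conditions a community synthesizes its membranes under.

## Worked example

```python
from iplome import parse_formula, zc, adduct_mz
from iplome.database import (ChainConstraints, generate_database,
    read_component_table, read_unique_component_table,
    starter_component_path, starter_unique_component_path)
from iplome.annotate import read_rules, default_rules_path
from iplome.simulate import random_scenario, simulate_dataset, recovery_report
from iplome.pipeline import run_pipeline

print(zc(parse_formula("CH4")), zc(parse_formula("CO2")))   # -4.0 4.0

pc = parse_formula("C42H84NO8P")                  # PC-DAG 34:0
print(round(pc.mass, 4), round(adduct_mz(pc.mass, "[M+H]+"), 4))
# 761.5935 762.6007

components = read_component_table(starter_component_path())
uniques = read_unique_component_table(starter_unique_component_path())
db = generate_database(components, uniques, ChainConstraints())
print(len(db))                                    # 123748

rules = read_rules(default_rules_path())
scenario = random_scenario(db, n_lipids=50, seed=42, mz_noise_ppm=2.5, area_cv=0.05)
dataset = simulate_dataset(scenario, db)
annotations, result = run_pipeline(dataset, db, rules, tol_ppm=7.5)
print(recovery_report(dataset.truth, result))
# {'precision': 0.96, 'recall': 0.96, 'n_correct': 48,
#  'rmse_ng_l': 0.177, 'median_rel_err': 0.018}
print(annotations["provenance"].value_counts().to_dict())
# {'direct': 46, 'no-hydroxylation-default': 2, 'neighbor-transfer': 2}
```

Reading the numbers: the starter component tables generate a database
of 123,748 ionized theoretical lipids. A simulated 50-lipid community
with 2.5 ppm mass noise and 5% area noise is annotated back to the
correct species for 48 of 50 features (the two misses are structural
isomers indistinguishable from the modeled evidence), and recovered
concentrations sit within ~2% of truth at the median. Provenance counts
show how each isomer decision was made. At zero noise with complete MS2
evidence the pipeline inverts the forward model exactly.

The same steps are available from the shell:

```sh
iplome build-db -o db.csv
iplome simulate --db db.csv --out-dir sim/
iplome annotate --db db.csv --features sim/features.csv --ms2 sim/ms2.mgf -o ann.csv
iplome quantify --annotations ann.csv --features sim/features.csv \
    --blanks sim/blanks.csv --is-responses sim/is_responses.csv \
    --dilutions sim/dilutions.csv --volumes sim/volumes.csv -o quant.csv
iplome stats --quant quant.csv --db db.csv --out-dir stats/
```

See `docs/methods.md` for the models, conventions (chain spacing rule,
Zc partition table, tie-breaks) and limitations.

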