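# emitra

**Read-across estimation of chemical manufacturing process emissions.**

Exposure assessment of a new chemical needs to know how much of each species
its manufacturing process releases to air, water and land — but measured
emission data rarely exist for a process that has not been built yet.
`emitra` fills that gap the way toxicologists fill toxicity data gaps:
by *read-across* from structurally analogous chemicals whose manufacturing
processes **do** have measured emissions.

Given a target chemical (as SMILES), a library of candidate source
chemicals, their physicochemical property tables and per-process measured
emission factors (kg emitted per kg product), the package:

1. identifies the target chemical and its process;
2. characterizes the process (role-annotated participants, catalyst class,
   conditions, pollution controls);
3. ranks candidate analogues by Tanimoto fingerprint similarity
   T(A,B) = |A∩B| / |A∪B| and validates structural categories (same
   functional groups; adjacent members differ by ≤ 2 carbon atoms);
4. analyses property data gaps and fills them by within-category
   least-squares trends (log₁₀ domain for vapor pressure and water
   solubility);
5. checks process compatibility (catalyst class must match; large
   temperature/time/control differences raise warnings);
6. estimates the target's emissions under one of four quantitative modes —
   **closest** (carry over the closest analogue's value, scaled by an
   overall read-across factor Π or geometric mean of per-property ratios
   fᵢ = xᵢ,target / xᵢ,source), **trend** (log-linear regression of emission
   on carbon count across a category), **average**, or **conservative**
   (worst case = highest emission);
7. decides whether a second iteration is warranted, then grades the
   uncertainty **low / moderate / high** from structural similarity,
   process similarity, source-data basis and any trend-filling or
   extrapolation.

Every estimate carries its complete provenance (source chain, factors,
mode) and can be re-derived bit-for-bit by `audit_estimate`.

## Worked example: cumene → p-cymene

p-Cymene (4-isopropyltoluene) and cumene (isopropylbenzene) are both made
by solid-acid-catalysed alkylation with propylene — toluene + propylene
and benzene + propylene respectively. Cumene's process has measured air
emission factors; p-cymene's does not. The embedded fixture carries the
property table and emissions, so the whole one-to-one read-across is:

```sh
cat > run.yaml <<EOF
target_id: p-cymene
use_case_study: true
output_dir: out
EOF
emitra estimate --config run.yaml --mode closest --factor-rule unity
```

which prints

```
report: out/report.json
estimates: out/estimates.tsv
  toluene: 5.9e-06 kg/kg (closest, factor 1)
  propylene: 7.8e-06 kg/kg (closest, factor 1)
  p-cymene: 1.9e-05 kg/kg (closest, factor 1)
uncertainty: low
```

Reading the output: cumene was retrieved as the closest analogue, the two
processes were judged compatible (same catalyst class, no warnings), and
each measured cumene-process emission row was carried across with its
species relabelled through the role mapping — benzene (aromatic reactant)
→ toluene, propylene → propylene, cumene (product) → p-cymene. With factor
rule `unity` the values transfer unchanged, reflecting the judgement that
the property differences between the pair are not significant; with
`--factor-rule geomean` the estimates would instead be scaled by the
vapor-pressure ratio 1.55/4.6 ≈ 0.337. The `low` grade says all
uncertainty drivers are favourable: a close structural analogue, a nearly
identical process, and measured (not estimated) source data.

Analogue ranking alone is also exposed:

```sh
emitra fixtures export fixture
emitra analogs --target "CC(C)c1ccc(C)cc1" --library fixture/library.smi --cutoff 0
```

```
rank    id                          similarity
1       p-cymene                    1.0000
2       cumene                      0.5909
3       1,4-diisopropylbenzene      0.5636
...
```

`emitra simulate` generates synthetic homologous alkylbenzene series with
known (log-)linear property and emission laws for validating the trend
mode, and `emitra validate` checks input CSV/JSON files against the
schemas.

## Layout

| module | contents |
| --- | --- |
| `emitra.chem` | SMILES parsing, formulas, molecular weight, fingerprints, Tanimoto |
| `emitra.analogs` | analogue ranking, category validation, grouping modes |
| `emitra.properties` | gap analysis, trend filling |
| `emitra.engine` | compatibility, role mapping, factors, the four estimation modes, audit |
| `emitra.uncertainty` | low/moderate/high grading |
| `emitra.framework` | the seven-step workflow |
| `emitra.datasets` | embedded case study, synthetic series generator |
| `emitra.io` / `emitra.cli` | CSV/JSON/YAML formats and the `emitra` command |

See `docs/methods.md` for the modelling choices, defaults and limitations.
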