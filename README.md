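# progchain

**Disease progression chains from integrated multi-evidence disease networks.**

A disease rarely evolves in isolation: colitis can progress to acute kidney
injury, which can lead to polyuria, then hyponatremia, and finally respiratory
insufficiency. `progchain` is a toolkit for inferring such *progression
chains* — ordered sequences of diseases joined by prior–posterior (predecessor
→ successor) relations — from heterogeneous biomedical evidence. It is aimed
at systems-biology and clinical-informatics researchers who have
disease–protein associations, pathway data, comorbidity counts and/or
pre-extracted literature relations, and want ranked, directed multi-step
hypotheses between any two diseases.

## Method

Four directed, weighted disease networks are built, one per evidence layer:

| Layer | Evidence | Weight |
|-------|----------|--------|
| ADN | shared proteins | cosine of the disease–protein bit vectors, `w_ij = d_i·d_j / (‖d_i‖‖d_j‖)`, k-NN sparsified, bidirected |
| pDPN | pathway flow | `w_ij = φ(F_ij − F_ji)·max(F_ij, F_ji)` where `F_ij` counts gene reactions running from disease *i*'s exclusive genes into disease *j*'s gene set (`φ(u) = 1` if `u > 0`, else 0) |
| cDPN | clinical history | relative risk `RR(A,B) = p(B\|A)/p(B\|¬A)` from patient counts; dominant direction weighted by the ratio of relative risks `RRR = RR(A,B)/RR(B,A)` |
| tDPN | literature | per-term document–clause frequency `DCF = df·log(cf+1)`, scaled by a term-strength lexicon `α_t`; `w_ij = ψ(s_ij − s_ji)` with `s_ij = Σ_t α_t·DCF_t` |

Raw weights are normalized to (0, 1] by the per-network maximum, and the
layers are merged edge-wise (strongest evidence wins by default).
Association-only edges carry no direction, so they are penalized by a factor
β ∈ (0, 1] before search.

Weights become distances via `dist(i, j) = 1 − w_ij`, and the *k* most
plausible chains between a source and a target are found by a deviation-loop
search: one reverse Dijkstra pass from the target yields the exact remaining
distance `h(v)` for every node, forward A* with `f(v) = g(v) + h(v)` finds
each shortest path, and successive chains come from cutting arcs of the
chains already found and re-searching (the heuristic is computed once and
reused — cuts can only lengthen paths, so it stays admissible). Each chain
of length *l* with arc weights `w` is ranked by the progression score

```
PS = δ · exp(−l + Σw)
```

which rewards strong relations and penalizes long chains. Chains built
*without* clinical evidence can be validated against held-out comorbidity
data: an arc `i → j` counts as clinically supported when `RRR(i, j) > 1`.

A synthetic-data module generates all four raw evidence layers from a planted
ground-truth progression DAG, so the whole pipeline can be exercised,
calibrated and tested with no external data.

## Worked example

Build the bundled toy network around the colitis → respiratory-insufficiency
route and ask for the five best chains:

```bash
progchain fixture colitis-toy --outdir fx
progchain chains --network fx/edges.tsv \
    --source Colitis --target Respiratory_Insufficiency \
    --k 5 --delta 100 -o chains.tsv
```

`chains.tsv` then contains (scores rounded):

```
rank  chain                                                             length_l  progression_score
1     Colitis|Acute_Kidney_Injury|Polyuria|Hyponatremia|Respiratory_Insufficiency          4  54.88
2     Colitis|Diabetes_Insipidus|Polyuria|Hyponatremia|Respiratory_Insufficiency           4  52.20
3     Colitis|Polydipsia|Polyuria|Hyponatremia|Respiratory_Insufficiency                   4  47.24
4     Colitis|Acute_Kidney_Injury|Oliguria|Diabetes_Insipidus|Polyuria|...                 6  24.66
5     Colitis|Renal_Colic|Oliguria|Diabetes_Insipidus|Polyuria|...                         6  19.20
```

The three 4-step chains share the polyuria → hyponatremia →
respiratory-insufficiency tail and differ in how they reach polyuria; the
two 6-step detours through oliguria score markedly lower because PS decays
exponentially with chain length. A direct route does not exist in the
network — the method's point is exactly to surface such multi-step links.

The same workflow runs end to end on synthetic raw evidence:

```bash
progchain simulate --seed 7 --outdir world/
progchain build-adn  --associations world/associations.tsv --knn 10 -o adn.tsv
progchain build-pdpn --membership world/pathway_membership.tsv \
                     --reactions world/pathway_reactions.tsv -o pdpn.tsv
progchain build-cdpn --totals world/comorbidity_totals.tsv \
                     --singles world/comorbidity_singles.tsv \
                     --pairs world/comorbidity_pairs.tsv -o cdpn.tsv
progchain build-tdpn --evidence world/text_evidence.tsv \
                     --alpha-table world/term_strengths.tsv -o tdpn.tsv
progchain integrate --inputs adn.tsv,pdpn.tsv,cdpn.tsv,tdpn.tsv \
                    --combine max --beta 0.5 -o int.tsv
progchain stats int.tsv
```

See `docs/methods.md` for the model details, parameter defaults and the
synthetic-world design.

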