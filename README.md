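# hfrisk

Hospital-acquired (nosocomial) infections spread between departments, and a
facility's department configuration shapes that spread. `hfrisk` implements a
hybrid multi-criteria decision analysis that helps hospital managers decide
which departments to eliminate — or target with reinforced hygiene policy —
when rearchitecting a healthcare facility: it combines a cross-infection
influence analysis (DEMATEL) with a managerial weighted-sum ranking (WSM),
fed by rank-weighted expert panels. It is aimed at decision analysts and
infection-control teams who have expert judgment data rather than
transmission measurements.

## Method

**Expert aggregation.** Each expert *k* supplies an n×n pairwise influence
matrix X^(k) on a 0–4 scale (how strongly department *i* transmits infection
to department *j*; zero diagonal) and carries an integer rank weight r_k
reflecting expertise. The consensus direct-relation matrix is the
rank-weighted mean

    Z_ij = Σ_k r_k X_ij^(k) / Σ_k r_k.

**DEMATEL.** Z is normalized by its largest row sum, D = Z/S with
S = max_i Σ_j Z_ij, and the total-relation matrix accumulates direct plus all
indirect influence paths:

    T = D (I − D)⁻¹ = Σ_{k≥1} D^k.

Row sums R_i measure influence dispatched, column sums C_i influence
received; R−C > 0 marks a *cause* (net transmitter), R−C < 0 an *effect*
(net receiver). The extremes of R−C are the master dispatcher and master
receiver. Both strong causes and strong receivers are high-risk.

**Modified WSM.** Managerial criteria weighted 0–100 are normalized,
W′_y = W_y / Σ W_y, and each department is scored 0–100 per criterion (100 =
strongest case for elimination). The DEMATEL result is mapped to a 0–100
infection-risk criterion, appended with raw weight 100, and all weights are
re-normalized jointly. Departments are ranked by the weighted sum
WS(A_x) = Σ_y W′_y V_yx; the top of the ranking is the elimination shortlist.

## Worked example

Replay the packaged case study — a 20-department trauma hospital whose
published total-relation and WSM tables ship as fixtures:

```python
from hfrisk import PipelineConfig, run_pipeline

ranking = run_pipeline(PipelineConfig(fixture="bahonar"))
print("dispatcher:", ranking.cause_effect.master_dispatcher)
print("receiver:  ", ranking.cause_effect.master_receiver)
print("WS(ED10) =", round(ranking.wsm_result.totals["ED10"], 2))
print("shortlist:", ranking.shortlist)
```

prints

```
dispatcher: ED5
receiver:   ED12
WS(ED10) = 43.56
shortlist: ('ED10', 'ED17', 'ED18', 'ED11')
```

ED5 (ICU2) dispatches the most net cross-infection influence and ED12 (jaw
and face surgery) receives the most, so both are flagged high-risk; the
weighted-sum shortlist proposes Hematology/Oncology 1, CT scanning,
Radiology and Hematology/Oncology 2 for elimination or reinforced hygiene.

The same pipeline runs on your own CSVs (or synthetic data) from the shell:

```bash
hfrisk simulate --out case/ --seed 7        # synthetic panel + matrices
echo "input_dir: case/" > cfg.yaml
hfrisk pipeline --config cfg.yaml
hfrisk dematel --matrix case/influence_I1.csv --out out/
```

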