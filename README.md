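# pestbudget

Bioeconomic decision support for insect pest management. Given the
probability that a pest outbreak occurs and the probability that the pest is
resistant to an insecticide, `pestbudget` computes the **expected yield** and
**expected net revenue** of coded management scenarios — combinations of
variety traits, spray policy and scouting — so that farmers, extension
agronomists and IPM researchers can compare tactics such as host-plant
resistance, prophylactic spraying and rescue applications on an expected-value
basis. The package ships a complete 2018 Iowa soybean-aphid
(*Aphis glycines*) case study as its default configuration.

## Model

A season is a two-stage lottery. An outbreak (a pest population exceeding the
economic threshold) occurs with probability *p*ₒ; given an outbreak the
population is wild-type, insecticide-resistant, or cross-resistant with
conditional probabilities *p*_w, *p*_s, *p*_c (summing to 1). The expected
fraction of attainable yield under a scenario is

```
EY = pₙ + pₒ · Σₜ pₜ · fₜ ,   fₜ = 1 if management is effective against class t,
                               fₜ = q otherwise (no management or failed management)
```

where *p*ₙ = 1 − *p*ₒ and *q* is the fraction of yield retained when an
outbreak goes unmanaged (0.873 for aphid-susceptible soybean, i.e. a 12.7%
loss; 1 for *Rag*-gene aphid-resistant varieties). Management is effective
when the variety is aphid-resistant or when at least one applied insecticide
belongs to a mode-of-action group the realized population does not survive;
a rescue application fires only in scenarios with efficacy scouting, and only
when the first product failed. Expected net revenue is the partial budget

```
E(R) = E(Y) · E(P) − E(C),     E(Y) = EY · Y
```

with *Y* the attainable yield (kg/ha), *E(P)* the expected crop price
(USD/kg) and *E(C)* the expected costs that differ between scenarios (seed,
herbicide product, insecticide product and application weighted by their
expected counts, in-season scouting). Because E(R) is affine in *p*ₒ and in
*p*_s, break-even probabilities between two scenarios are solved exactly in
closed form.

Scenarios are five-letter codes (see `pestbudget scenarios list`): variety
aphid trait S/R, herbicide trait H/C, spray policy X/P/T, scouting N/E/M,
pest type W/I. `SHPN-W` is a susceptible herbicide-tolerant variety sprayed
prophylactically against a wild-type pest; `RCXN-I` is an aphid-resistant
conventional variety facing insecticide-resistant aphids with no spray.

## Worked example

Evaluate the aphid-resistant variety scenario under the bundled 2018 Iowa
configuration (attainable yield 3537 kg/ha, price 0.33 USD/kg, outbreak
probability 0.435 for a high-risk location):

```
$ pestbudget evaluate --scenario RCXN-W
scenario                RCXN-W
p_outbreak              0.4350
expected yield fraction 1.0000
expected yield          3537.00 kg/ha
expected cost           230.17 USD/ha
expected net revenue    937.04 USD/ha
cost audit:
               item           trigger  unit_cost  expected_units  expected_cost
herbicide_product_C herbicide_product   118.6100          1.0000       118.6100
           seed_R.C              seed   111.5600          1.0000       111.5600
```

Host-plant resistance protects the full yield (EY = 1 at any outbreak
probability) and its only scenario-varying costs are conventional-herbicide
product and aphid-resistant seed, so it nets 937.04 USD/ha — the highest of
the eight case-study scenarios. The break-even probability of
pyrethroid-resistant aphids at which a lone pyrethroid stops out-earning no
management:

```
$ pestbudget breakeven --a SHPN-I --b SHXN-I --axis resistance
scenario_a    SHPN-I
scenario_b    SHXN-I
axis          resistance_probability
crossing      0.4751
crossing_pct  48%
favored_above SHXN-I
```

Spraying a pyrethroid remains the better decision until the chance of
pyrethroid resistance reaches about 48%; above that, accepting the outbreak
loss nets more. Probability sweeps (`pestbudget sweep --axis outbreak --out
sweep.csv`) and one-factor sensitivity analyses (`pestbudget sensitivity
--preset price_avg`) write the corresponding tables.

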