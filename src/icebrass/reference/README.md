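# Reference data provenance

## trussell_west_coefficients.csv

Trussell's regression coefficients for the children-ever-born /
children-dead method, Coale-Demeny **West** family: per maternal five-year
age group i, the multiplier turning the proportion of children dead d(i)
into a probability of dying is

    k_i = a_i + b_i * (P1/P2) + c_i * (P2/P3)

where P1, P2, P3 are mean parities of women 15-19, 20-24, 25-29.
Source: United Nations (1983), *Manual X: Indirect Techniques for
Demographic Estimation*, Table 47 (West model). Transcribed verbatim;
validated in the test suite against the manual's Panama 1976 worked
example.

## west_lx_levels_synthetic.csv

**Synthetic stand-in** for a West-family l(x)-by-level page: child
survival l(x), x in {1, 2, 3, 5, 10, 15, 20}, at integer levels 1..24
(higher level = higher survival), for `female` and `both`-sexes schedules.
Generated by `icebrass.lifetables.build_synthetic_west_lx()` (see its
docstring for the construction); the published Coale-Demeny pages are not
redistributable here. Level numbers are internally consistent across the
whole package but are not digit-for-digit comparable with published West
levels.

## _checksums.json

SHA-256 digests of the two CSVs above; loaders verify them at read time.
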