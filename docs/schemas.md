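# CSV schemas

All tables are comma-separated UTF-8 with a header row and '.' decimals.
Units: masses kg N, areas ha, rates kg N ha⁻¹ yr⁻¹ unless noted.

## Panel tables

**land_use.csv** — one row per district-year
`district_id, year, net_cropped_area, gross_cropped_area, district_area, cropland_fraction`
(`gross_cropped_area ≥ net_cropped_area`; `cropland_fraction ∈ [0, 1]`,
with `cropland_fraction × district_area` consistent with the cropped area)

**fertilizer.csv** — `district_id, year, total_n_applied` (kg N yr⁻¹, district total)

**crops.csv** — `district_id, year, crop_id, harvested_area, production`
(production kg yr⁻¹; zero wherever harvested_area is zero)

**livestock.csv** — `district_id, census_year, category_id, headcount`
(census years on a 5-year grid; categories: cattle, buffalo, poultry,
chickens, pigs, goats, sheep)

## Coefficient tables

**bnf_coefficients.csv** — `crop_id, pct_ndfa, nhi, bgn, area_rate`
(pct_ndfa ∈ [0, 1]; area_rate kg N ha⁻¹ yr⁻¹; non-fixing crops carry zeros)

**n_content.csv** — `crop_id, source, n_content`
(source ∈ {FAO, BOUWMAN}; n_content kg N per kg harvested product, < 0.2)

**manure_coefficients.csv** —
`category_id, n_rate, tam, f_mt_irrigated, f_mo_irrigated, f_loss_irrigated, f_mt_rainfed, f_mo_rainfed, f_loss_rainfed, am_cn, am_cl, am_fl`
(n_rate kg N (1000 kg animal mass)⁻¹ day⁻¹; tam kg head⁻¹; all f_*/am_*
fractions in [0, 1]; am_cn + am_cl + am_fl ≤ 1)

## Geography

**centroids.csv** — `district_id, latitude, longitude` (degrees; lon in [−180, 360))

**region_mapping.csv** — `district_id, scheme, region_id`
(scheme ∈ {state, basin, subbasin, national}; one region per district per scheme)

## Gridded fields

Long-format CSV plus a `<file>.csv.meta.json` sidecar
(`{"name": ..., "units": ..., "time_dim": "time"|"year"}`).

**deposition.csv** — `time, lat, lon, value` (monthly stamps;
units `kg N ha-1 month-1`, or `kg m-2 s-1` converted on read)

**manure_grid.csv** — `year, lat, lon, value` (units `kg N ha-1 yr-1` of NCA)

## Outputs

**members/surplus_<member_id>.csv** — `district_id, year, surplus_kgN_ha`

**summary_district.csv / summary_<scheme>.csv** —
`district_id|region_id, year, mean, q1, q3, iqr, sd, complete`

**provenance.json** — package version, run config, ensemble metadata
(methods, extension and interpolation rules, production-system shares,
member composition), validation warnings.
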