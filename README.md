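# stillmetrics

Country-level stillbirth indicators for epidemiologists, health economists
and global-health analysts: consistent stillbirth-rate definitions with
exact interconversion, stillbirths-adjusted life expectancy (SALE), and the
years of life lost (YLL/DALY) attributable to stillbirths — plus regional
and income-group aggregation and a seeded synthetic-panel generator for
testing pipelines without any data download.

## The quantities

Two stillbirth rates circulate, differing only in denominator. With *SB*
stillbirths, *LB* live births and *TB = SB + LB* total births:

- **SLBR** = 1000·SB/LB — stillbirths per 1000 *live* births (the ICD
  "fetal death ratio"), the same denominator as the neonatal mortality
  rate NMR = 1000·NM/LB;
- **STBR** = 1000·SB/TB — stillbirths per 1000 *total* births (the ICD
  "fetal death rate"), the basis on which global estimates are published.

They interconvert exactly, without the underlying counts:

    SLBR − STBR = SLBR·STBR/1000          (gap identity)
    SLBR = 1000·STBR/(1000 − STBR)        STBR = 1000·SLBR/(1000 + SLBR)

Because SLBR shares its denominator with NMR, the ratio SLBR:NMR equals the
count ratio SB:NM — so the relative burden of stillbirth versus neonatal
death can be read straight off the two rates, which STBR:NMR (smaller by
the factor LB/TB) does not permit.

Sharing the live-birth denominator also lets SLBR fold stillbirths into
life expectancy. 1000 live births embody 1000·LE person-years; spreading
them over the 1000 + SLBR total births behind them gives

    SALE = 1000·LE/(1000 + SLBR),   LE − SALE = SLBR·LE/(1000 + SLBR)

and the years of life lost to stillbirths are the decrement times the
live-birth count:

    YLL = (LE − SALE)·LB   person-years.

For example, LE = 71 years with SLBR = 13 gives SALE = 71000/1013 ≈ 70
years: counting stillbirths costs this country one year of life expectancy.

Group summaries distinguish *pooled* rates (summed counts — the group as
one population) from *cross-country* statistics (unweighted mean, sample
SD, and coefficient of variation CV = 100·SD/mean of member-country
values).

## Worked example

Input is a delimited panel (CSV or TSV, auto-detected) with columns
`country, region, income_group, year, stillbirths, neonatal_deaths,
neonatal_mortality_rate, life_expectancy` and optionally `iso3,
live_births` (when `live_births` is absent it is back-derived as
1000·NM/NMR). With `demo.csv` holding three 2015 rows:

```csv
country,region,income_group,year,stillbirths,neonatal_deaths,neonatal_mortality_rate,life_expectancy,live_births
Pakistan,SA,lower-middle+low,2015,240260,242000,45.42,66.38,5328671
Nigeria,SSA,lower-middle+low,2015,312761,240000,34.39,53.05,6979287
Iceland,DR,high+upper-middle,2015,8,9,2.0,82.5,4500
```

```
$ stillmetrics rates --input demo.csv
country,year,slbr_per1000,stbr_per1000,nmr_per1000,sb_nm_ratio_x100
Pakistan,2015,45.09,43.14,45.41,99.3
Nigeria,2015,44.81,42.89,34.39,130.3
Iceland,2015,1.78,1.77,2.0,88.9
```

Pakistan loses 45.09 pregnancies past 28 weeks per 1000 live births — about
as many as its neonatal deaths (ratio 99.3 per 100) — while the same counts
expressed per total births read 43.14. Iceland's two rates are nearly
indistinguishable: the gap identity makes the distinction matter exactly
where rates are high.

```
$ stillmetrics sale --input demo.csv
country,year,le_years,sale_years,decrement_years
Pakistan,2015,66.38,63.52,2.86
Nigeria,2015,53.05,50.77,2.28
Iceland,2015,82.5,82.35,0.15
```

Counting stillbirths lowers Pakistan's life expectancy by 2.86 years but
Iceland's by only 0.15 — the adjustment widens cross-country gaps.

```
$ stillmetrics summarize --input demo.csv --group-by income --yll-units 1e6
group,n_countries,pooled_slbr_per1000,sb_nm_ratio_x100,mean_slbr_per1000,...,total_yll_millions
high+upper-middle,1,1.78,88.9,1.78,...,0.0
lower-middle+low,2,44.93,114.7,44.95,...,31.1
World,3,44.92,114.7,30.56,...,31.1
```

The two poorer countries account for all 31.1 million person-years lost in
this toy panel. Other subcommands: `yll` (per-country and group totals),
`convert` (STBR↔SLBR on any column), `synth` (seeded synthetic panel).
The same operations are available as library functions
(`stillmetrics.compute_sale`, `pooled_rates`, `summarize`, …).

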