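id,author_year,description,rating
avail_serving_enforce,Miller and Levy 2000,Enforcing laws against serving intoxicated patrons,B
avail_mlda19,Miller 2001; Kypri et al. 2006,Raising minimum legal drinking age to 19 yrs,A
avail_server_training,Miller 2001,Mandatory server training to deny service to intoxicated and underage patrons,C
avail_underage_enforce,Elder et al. 2007,Enforce underage drinking laws,C
avail_outlet_density,Campbell 2009; Norstrom 2010,10% alcohol outlet density reduction,B
avail_sales_hours,Hahn et al. 2010; Middleton 2010,10 fewer sales hours/week,B
avail_liability,Rammohan et al. 2011,Licensed establishment liability for harm caused by over-servicing patrons,B
mkt_ad_ban,Cobiac et al. 2009,Alcohol advertising ban,B
mkt_tv_ad_ban,Norstrom et al. 2010,TV alcohol advertising ban,C
price_min_095,Meng 2013,Minimum price for alcohol of A$0.95 per drink,C
price_volumetric_same_deadweight,Byrnes 2012,"Same tax per liter of ethanol on all alcohol, no change in total liters sold",B
price_volumetric_same_revenue,Byrnes 2012,"Same tax per liter of ethanol on all alcohol, no change in total tax revenue",B
price_volumetric_spirits_rate,Byrnes 2012,Spirits tax per liter of ethanol on all alcohol,B
price_wine_excise_beer_rate,Byrnes 2010,"Equal tax rate for beer and wine, higher rate for spirits & premised drinks",A
dd_alr,Miller and Levy 2000,Administrative license revocation,A
dd_alr_breath,Miller and Levy 2000,Law to allow administrative license revocation based on breath testing,A
dd_interlock_permitted,Miller and Levy 2000,Alcohol testing ignition interlock permitted,A
dd_rbt_raise,Miller 2001,Intensive random breath testing,A
dd_zero_tolerance_u18,Miller 2001,Zero alcohol tolerance for drivers under 18 yrs,A
dd_mass_media,Elder 2004,Mass media campaign to reduce drink driving,B
dd_saturation_patrols,Fell 2008,Saturation patrols plus media campaign,C
dd_impoundment,Miller and Hendrie 2013,Vehicle impoundment for drink driving offenses,A
dd_house_arrest,Miller and Hendrie 2013,Electronic house arrest for drink driving offenses,A
dd_probation,Miller and Hendrie 2013,Intensive probation for drink driving offenses plus treatment,A
dd_dui_court,WSIPP 2017,Driving under the influence court,A
dd_interlock_mandated,Teoh 2018,Alcohol testing ignition interlock mandated for all offenders,B
dd_ridesharing,Miller 2020,Subsidized Ridesharing,B
wk_prime_for_life,Cook et al. 2003,Prime for Life employer-sponsored web-based health promotion program,B
wk_team_awareness,Bennett et al. 2004,Team Awareness program (retail and restaurant workers),B
wk_team_resilience,Bennett et al. 2010,Team Resilience: an adaptation of Team Awareness for workers under age 26 years,B
wk_prevent,Spicer and Miller 2016,PREVENT: facilitated small-group employee discussions for young workers,B
hs_screen_primary,WSIPP 2017,Screening for heavy drinking in primary care setting and brief motivational intervention,A
hs_screen_inpatient,WSIPP 2017,Screening for heavy drinking in hospital inpatient setting and brief motivational intervention,A
hs_screen_ed,WSIPP 2017,Screening for heavy drinking in emergency department care setting and brief motivational intervention,A
yd_adolescent_transitions,Aos 2004 et al.,"Adolescent Transitions, ages 10-18",A
yd_across_ages,Hansen et al. 2004,"Across Ages, ages 9-13",A
yd_social_competence,Hansen et al. 2004,"Social Competence Promotion, ages 11-14",C
yd_communities_that_care,Kuklinski et al. 2015,Communities That Care,B
yd_strengthening_families,Spoth et al. 2002; WSIPP 2017,"Strengthening Families Program, ages 12-13",A
yd_caring_school,WSIPP 2017,"Caring School Community, ages 9-13",C
yd_good_behavior_game,WSIPP 2017,"Good Behavior Game, ages 6-9",B
yd_guiding_good_choices,WSIPP 2017,"Guiding Good Choices (Preparing for Drugfree Years), ages 12-13",A
sb_family_matters,Aos et al. 2004,"Family Matters, ages 12-14",B
sb_all_stars,WSIPP 2017,"All Stars, ages 11-14",B
sb_life_skills,WSIPP 2017,"Life Skills Training, 3-year program, ages 13-16",A
sb_positive_action,Beets 2009; WSIPP 2017,"Positive Action, ages 8-14",A
sb_project_northland,WSIPP 2017,"Project Northland, 3-year program, ages 12-15",B
sb_project_star,WSIPP 2017,"Project STAR, 2-year program, ages 12-15",B
sb_toward_no_drugs,WSIPP 2017,"Project Toward No Drugs, ages 15-19",B
sb_too_good_for_drugs,WSIPP 2017,Too Good for Drugs,B
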