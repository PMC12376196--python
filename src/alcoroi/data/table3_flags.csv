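id,uniform_benefits,other_modifications,costs_computed,demonstration_discount
avail_serving_enforce,False,False,False,True
avail_mlda19,True,False,False,False
avail_server_training,False,True,False,True
avail_underage_enforce,False,False,True,False
avail_outlet_density,False,False,True,False
avail_sales_hours,False,False,True,False
avail_liability,False,False,True,False
mkt_ad_ban,True,True,False,False
mkt_tv_ad_ban,False,False,True,False
price_min_095,True,True,False,False
price_volumetric_same_deadweight,True,False,True,False
price_volumetric_same_revenue,True,False,True,False
price_volumetric_spirits_rate,True,False,True,False
price_wine_excise_beer_rate,True,False,True,False
dd_alr,False,False,False,False
dd_alr_breath,False,False,False,False
dd_interlock_permitted,True,False,False,False
dd_rbt_raise,False,False,False,False
dd_zero_tolerance_u18,False,False,False,False
dd_mass_media,False,False,True,False
dd_saturation_patrols,False,False,True,False
dd_impoundment,False,False,False,False
dd_house_arrest,False,False,False,False
dd_probation,False,False,False,False
dd_dui_court,True,False,False,False
dd_interlock_mandated,False,False,True,False
dd_ridesharing,False,False,True,False
wk_prime_for_life,False,False,True,False
wk_team_awareness,False,False,True,False
wk_team_resilience,False,False,True,False
wk_prevent,False,False,True,False
hs_screen_primary,True,False,False,False
hs_screen_inpatient,True,False,False,False
hs_screen_ed,True,False,False,False
yd_adolescent_transitions,False,False,True,False
yd_across_ages,False,False,True,False
yd_social_competence,False,False,True,False
yd_communities_that_care,True,False,False,True
yd_strengthening_families,True,True,False,True
yd_caring_school,False,False,True,False
yd_good_behavior_game,False,False,True,False
yd_guiding_good_choices,True,True,False,True
sb_family_matters,False,False,True,True
sb_all_stars,False,False,True,True
sb_life_skills,True,True,False,True
sb_positive_action,True,False,False,True
sb_project_northland,True,True,False,True
sb_project_star,True,True,False,True
sb_toward_no_drugs,False,False,True,True
sb_too_good_for_drugs,False,False,False,False
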