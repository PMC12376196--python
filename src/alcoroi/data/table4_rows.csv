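id,name,category,cost_per_unit,denominator,resource_savings,intangible_savings,total_savings,bcr_printed,cost_per_qaly_printed,quality_rating,demonstration_stage,flags
avail_serving_enforce,Enforce laws against serving intoxicated patrons,availability,1,driver,8,27,35,35.0,NET_SAVING,B,True,demonstration_discount
avail_mlda19,Raise minimum legal drinking age to 19 years,availability,401,youth,142,679,821,2.0,69355,A,False,uniform_benefits
avail_server_training,Mandatory server training to deny service to intoxicated and underage patrons,availability,100,driver,37,185,222,2.2,62231,C,True,other_modifications|demonstration_discount
avail_liability,Licensed establishment liability for harm caused by over-servicing patrons,availability,6,adult,5,20,25,4.2,8788,B,False,costs_computed
avail_underage_enforce,Enforce underage drinking laws,availability,4,youth,31,153,184,46.0,NET_SAVING,C,False,costs_computed
avail_outlet_density,10% alcohol outlet density reduction,availability,3095,per_1e6_population,2410,13626,16036,5.2,9151,B,False,costs_computed
avail_sales_hours,10% fewer sales hours/week,availability,7792,per_1e6_population,6026,34064,40090,5.1,9432,B,False,costs_computed
mkt_ad_ban,Alcohol advertising ban,marketing,1329,per_1e6_population,2167,7976,10144,7.6,NET_SAVING,B,False,uniform_benefits|other_modifications
mkt_tv_ad_ban,TV alcohol advertising ban,marketing,12372,per_1e6_population,9643,54501,64144,5.2,9114,C,False,costs_computed
price_min_095,Minimum price for alcohol of A$0.95 per drink,pricing,10,drinker_year,12,16,28,2.8,NET_SAVING,C,False,uniform_benefits|other_modifications
price_volumetric_same_revenue,"Volumetric tax on alcohol, same total tax revenue",pricing,-10,per_1e4_drinks,1,6,7,NO_COST,NET_SAVING,B,False,uniform_benefits|costs_computed
price_volumetric_same_deadweight,"Volumetric tax on alcohol, same deadweight loss",pricing,0.04,per_1e4_drinks,11,51,61,1537,NET_SAVING,B,False,uniform_benefits|costs_computed
price_volumetric_spirits_rate,Volumetric tax on alcohol at spirits tax rate,pricing,151,per_1e4_drinks,1651,7913,9564,63,NET_SAVING,B,False,uniform_benefits|costs_computed
price_wine_excise_beer_rate,Replace price-based wine tax with excise tax at beer rate,pricing,3,per_1e4_drinks,5,22,27,8.8,NET_SAVING,A,False,uniform_benefits|costs_computed
dd_alr,Administrative license revocation,drink_driving,4330,license_revoked,5265,30105,35370,8.2,NET_SAVING,A,False,
dd_alr_breath,Law to allow administrative license revocation based on breath testing,drink_driving,4065,license_revoked,6269,35797,42066,10.3,NET_SAVING,A,False,
dd_interlock_permitted,Alcohol-testing ignition interlock permitted,drink_driving,1912,vehicle_equipped,739,4041,4780,2.5,52855,A,False,uniform_benefits
dd_rbt_raise,Raise random breath test rate from 0.5 to 1/driver/year,drink_driving,21,driver,22,91,113,5.5,NET_SAVING,A,False,
dd_zero_tolerance_u18,Zero alcohol tolerance for drivers under 18 years,drink_driving,78,driver,93,471,564,7.2,NET_SAVING,A,False,
dd_mass_media,Mass media campaign to reduce drink driving,drink_driving,5389,per_1e3_population,5446,20056,25502,4.7,NET_SAVING,B,False,costs_computed
dd_saturation_patrols,Saturation patrols plus media campaigns,drink_driving,51406,per_1e4_drivers,40487,167137,207624,4.0,11890,C,False,costs_computed
dd_impoundment,Vehicle impoundment for drink driving offenses,drink_driving,1648,impoundment,603,2646,3248,2.0,71874,A,False,
dd_house_arrest,Electronic house arrest for drink driving offenses,drink_driving,2868,house_arrest,1960,1619,3579,1.2,102161,A,False,
dd_probation,Intensive probation for drink driving offenses plus treatment,drink_driving,1511,probation,1075,2506,3581,2.4,31684,A,False,
dd_dui_court,Driving under the influence court,drink_driving,3092,client,163,6846,7009,2.3,77853,A,False,uniform_benefits
dd_interlock_mandated,Alcohol testing ignition interlock mandated for all offenders,drink_driving,1912,vehicle_equipped,1794,9814,11608,6.1,NET_SAVING,B,False,costs_computed
wk_prime_for_life,Prime for Life employer-sponsored web-based health promotion program that includes substance abuse prevention,workplace,19,participating_worker,55,299,354,18.2,NET_SAVING,B,False,costs_computed
wk_team_awareness,"Team Awareness program to promote group cohesiveness, stress coping, and peer support that includes substance abuse prevention (retail and restaurant workers)",workplace,268,participating_worker,228,1245,1473,5.5,5828,B,False,costs_computed
wk_team_resilience,Team Resilience: an adaptation of Team Awareness for workers under age 26 years,workplace,269,participating_worker,445,2421,2865,10.6,NET_SAVING,B,False,costs_computed
wk_prevent,PREVENT: a facilitated set of employee discussions in small groups focused on recognising the need for and planning changes in substance use and financial management for young workers,workplace,494,participating_worker,209,1180,1389,2.8,43918,B,False,costs_computed
hs_screen_primary,Screening for heavy drinking in primary care setting and brief motivational intervention when indicated,health_sector,353,person_treated,439,3872,4311,12.2,NET_SAVING,A,False,uniform_benefits
hs_screen_inpatient,Screening for heavy drinking in hospital inpatient setting and brief motivational intervention when indicated,health_sector,129,person_treated,382,3376,3758,29.0,NET_SAVING,A,False,uniform_benefits
hs_screen_ed,Screening for heavy drinking in emergency department care setting and brief motivational intervention when indicated,health_sector,350,person_treated,313,2761,3074,8.8,2460,A,False,uniform_benefits
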