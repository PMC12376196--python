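id,name,category,cost_per_unit,denominator,resource_savings,intangible_savings,total_savings,bcr_printed,cost_per_qaly_printed,quality_rating,demonstration_stage,flags
yd_adolescent_transitions,"Adolescent Transitions: a parenting skills program combined with universal, indicated, and selective prevention, ages 10-18",youth_development,2035,student,456,2804,3260,1.6,134413,A,False,costs_computed
yd_across_ages,"Across Ages: a program to strengthen adult and youth bonds through mentoring, community service and family activities, ages 9-13",youth_development,2930,student,503,3008,3511,1.2,194624,A,False,costs_computed
yd_social_competence,"Social Competence Promotion: a program to enhance social competence to reduce the use of violence and improve conflict resolution, ages 11-14",youth_development,593,student,511,3140,3651,6.2,6232,C,False,costs_computed
yd_communities_that_care,"Communities That Care: needs assessment, followed by implementation of evidence-based youth interventions",youth_development,819,student,195,3598,3793,4.6,40145,B,True,uniform_benefits|demonstration_discount
yd_strengthening_families,"Strengthening Families Program, parent-child behavioral training designed to prevent substance use, ages 12-13",youth_development,1479,student,1783,29469,31252,21.1,NET_SAVING,A,True,uniform_benefits|other_modifications|demonstration_discount
yd_caring_school,"Caring School Community: program to build sense of school community, ages 9-13",youth_development,388,student,643,3350,3993,10.3,NET_SAVING,C,False,costs_computed
yd_good_behavior_game,"Good Behavior Game, classroom management strategy to teach youth to comply with rules, ages 6-9",youth_development,102,student,46,3157,3203,31.4,4064,B,False,costs_computed
yd_guiding_good_choices,"Guiding Good Choices (Preparing for Drugfree Years), parent-child behavioral training, ages 12-13",youth_development,1194,student,999,4325,5324,4.5,10830,A,True,uniform_benefits|other_modifications|demonstration_discount
sb_family_matters,"Family Matters: a family-focused program to reduce tobacco and alcohol use, ages 12-14",school_based,265,student,412,8039,8451,31.9,NET_SAVING,B,True,costs_computed|demonstration_discount
sb_all_stars,"All Stars: decision-making, goal setting, and peer pressure resistance skills training, ages 11-14",school_based,236,student,554,10146,10700,45.3,NET_SAVING,B,True,costs_computed|demonstration_discount
sb_life_skills,"Life Skills Training, 3-year program, ages 13-16",school_based,375,student,241,4591,4832,12.9,6756,A,True,uniform_benefits|other_modifications|demonstration_discount
sb_positive_action_3_8,"Positive Action: a school-wide positive behavior program aimed at improving social and emotional learning and school climate, grades 3-8",school_based,1969,student,3545,37310,40855,20.7,NET_SAVING,A,True,uniform_benefits|demonstration_discount
sb_positive_action_3_5,"Positive Action as above, grades 3-5",school_based,1063,student,936,12765,13701,12.9,2321,A,True,uniform_benefits|demonstration_discount
sb_project_northland,"Project Northland: school-based child-parent training, 3-years program, ages 12-15",school_based,670,student,328,9003,9331,13.9,8754,B,True,uniform_benefits|other_modifications|demonstration_discount
sb_project_star,"Project STAR: a school/family/community/media to prevent drug and alcohol use, 2-year program, ages 12-15",school_based,670,student,227,5640,5867,8.8,18195,B,True,uniform_benefits|other_modifications|demonstration_discount
sb_toward_no_drugs,"Project Toward No Drugs, ages 15-19 yrs. (high school)",school_based,303,student,308,1218,1526,5.0,0,B,True,costs_computed|demonstration_discount
sb_too_good_for_drugs,"Too Good for Drugs, school-based life skills, ages 12-14",school_based,139,student,98,583,681,4.9,16934,B,False,
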