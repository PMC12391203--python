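model variant : neck=two_joint,sc=on,torso=L5S1_T12L1
bodies        : 29
degrees of freedom : 48
total mass    : 75.000 kg
markers       : 57

body          mass kg   joint            kind        coordinates
pelvis          8.377   ground_pelvis    free6       pelvis_tx, pelvis_ty, pelvis_tz, pelvis_tilt, pelvis_list, pelvis_rotation
femur_r        10.582   pelvis_femur_r   ball3       hip_flexion_r, hip_adduction_r, hip_rotation_r
patella_r       0.037   femur_r_patella_r weld0       -
tibia_r         2.685   femur_r_tibia_r  pin1        knee_angle_r
fibula_r        0.562   tibia_r_fibula_r weld0       -
talus_r         0.075   tibia_r_talus_r  pin1        ankle_angle_r
calcn_r         0.802   talus_r_calcn_r  pin1        subtalar_angle_r
toes_r          0.150   calcn_r_toes_r   pin1        mtp_angle_r
femur_l        10.582   pelvis_femur_l   ball3       hip_flexion_l, hip_adduction_l, hip_rotation_l
patella_l       0.037   femur_l_patella_l weld0       -
tibia_l         2.685   femur_l_tibia_l  pin1        knee_angle_l
fibula_l        0.562   tibia_l_fibula_l weld0       -
talus_l         0.075   tibia_l_talus_l  pin1        ankle_angle_l
calcn_l         0.802   talus_l_calcn_l  pin1        subtalar_angle_l
toes_l          0.150   calcn_l_toes_l   pin1        mtp_angle_l
abdomen         7.650   l5s1             custom_rot3 lumbar_extension, lumbar_bending, lumbar_rotation*
thorax         13.534   t12l1            custom_rot3 thorax_extension, thorax_bending, thorax_rotation*
neck            1.324   c7t1             custom_rot3 neck_extension, neck_bending, neck_rotation*
head            3.972   c1skull          custom_rot3 skull_extension, skull_bending, skull_rotation*
clavicle_r      0.441   sc_r             universal2  sc_protraction_r, sc_elevation_r
scapula_r       1.030   ac_r             weld0       -
humerus_r       2.032   scapula_r_humerus_r ball3       arm_flex_r, arm_add_r, arm_rot_r
forearm_r       1.215   humerus_r_forearm_r pin1        elbow_flex_r
hand_r          0.458   forearm_r_hand_r custom_rot3 pro_sup_r, wrist_flex_r, wrist_dev_r
clavicle_l      0.441   sc_l             universal2  sc_protraction_l, sc_elevation_l
scapula_l       1.030   ac_l             weld0       -
humerus_l       2.032   scapula_l_humerus_l ball3       arm_flex_l, arm_add_l, arm_rot_l
forearm_l       1.215   humerus_l_forearm_l pin1        elbow_flex_l
hand_l          0.458   forearm_l_hand_l custom_rot3 pro_sup_l, wrist_flex_l, wrist_dev_l

driver coordinates: torso_rotation, head_rotation

(* constrained, ^ locked)
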