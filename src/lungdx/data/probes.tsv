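probe_id	gene	role	fusion_id	nominal_amount
ALK_5P_01	ALK	five_prime	.	.
ALK_5P_02	ALK	five_prime	.	.
ALK_5P_03	ALK	five_prime	.	.
ALK_3P_01	ALK	three_prime	.	.
ALK_3P_02	ALK	three_prime	.	.
ALK_3P_03	ALK	three_prime	.	.
FS_EML4-ALK_E13:A20	ALK	fusion_specific	EML4-ALK_E13:A20	.
FS_EML4-ALK_E6ab:A20	ALK	fusion_specific	EML4-ALK_E6ab:A20	.
FS_EML4-ALK_E20:A20	ALK	fusion_specific	EML4-ALK_E20:A20	.
FS_NPM1-ALK_N4:A20	ALK	fusion_specific	NPM1-ALK_N4:A20	.
FS_KIF5B-ALK_K24:A20	ALK	fusion_specific	KIF5B-ALK_K24:A20	.
RET_5P_01	RET	five_prime	.	.
RET_5P_02	RET	five_prime	.	.
RET_5P_03	RET	five_prime	.	.
RET_3P_01	RET	three_prime	.	.
RET_3P_02	RET	three_prime	.	.
RET_3P_03	RET	three_prime	.	.
FS_CCDC6-RET_C1:R12	RET	fusion_specific	CCDC6-RET_C1:R12	.
FS_KIF5B-RET_K15:R12	RET	fusion_specific	KIF5B-RET_K15:R12	.
FS_NCOA4-RET_N6:R12	RET	fusion_specific	NCOA4-RET_N6:R12	.
ROS1_5P_01	ROS1	five_prime	.	.
ROS1_5P_02	ROS1	five_prime	.	.
ROS1_5P_03	ROS1	five_prime	.	.
ROS1_3P_01	ROS1	three_prime	.	.
ROS1_3P_02	ROS1	three_prime	.	.
ROS1_3P_03	ROS1	three_prime	.	.
FS_SLC34A2-ROS1_S4:R32	ROS1	fusion_specific	SLC34A2-ROS1_S4:R32	.
FS_SDC4-ROS1_S2:R32	ROS1	fusion_specific	SDC4-ROS1_S2:R32	.
FS_CD74-ROS1_C6:R34	ROS1	fusion_specific	CD74-ROS1_C6:R34	.
FS_EZR-ROS1_E10:R34	ROS1	fusion_specific	EZR-ROS1_E10:R34	.
HK_GUSB	.	housekeeping	.	.
HK_TBP	.	housekeeping	.	.
HK_POLR2A	.	housekeeping	.	.
HK_TUBB	.	housekeeping	.	.
POS_A	.	pos_control	.	128
POS_B	.	pos_control	.	32
POS_C	.	pos_control	.	8
POS_D	.	pos_control	.	2
POS_E	.	pos_control	.	0.5
POS_F	.	pos_control	.	0.125
NEG_A	.	neg_control	.	.
NEG_B	.	neg_control	.	.
NEG_C	.	neg_control	.	.
NEG_D	.	neg_control	.	.
NEG_E	.	neg_control	.	.
NEG_F	.	neg_control	.	.
NEG_G	.	neg_control	.	.
NEG_H	.	neg_control	.	.
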