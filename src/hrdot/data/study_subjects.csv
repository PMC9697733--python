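subject_id,group,retinopathy,inl_dot_count,granule_count,elongated_count,mean_elongated_extent_um,near_ipl_count,near_ipl_pct,inside_inl_count,inside_inl_pct,near_opl_count,near_opl_pct,onl_dot_count,mean_onl_extent_um
1,patient,mNPDR,18,5,13,59,7,39,3,17,8,44,2,11
2,patient,mNPDR,14,2,12,79,6,43,0,0,8,57,0,
3,patient,mNPDR,13,3,10,51,6,46,1,8,6,46,11,24
4,patient,mNPDR,13,4,9,67,4,31,4,31,5,38,2,39
5,patient,mNPDR,7,0,7,115,2,29,0,0,5,71,2,11
6,patient,QPDR,13,6,7,63,2,15,7,54,4,31,4,30
7,patient,QPDR,12,2,10,183,1,8,3,25,8,67,1,22
8,patient,QPDR,15,3,12,82,6,40,7,47,2,13,3,29
9,control,,13,2,11,128,4,31,0,0,9,69,0,
10,control,,8,0,8,87,0,0,1,13,7,88,0,
11,control,,16,7,9,76,3,19,1,6,12,75,0,
12,control,,11,0,11,180,2,18,0,0,9,82,3,11
13,control,,13,0,13,121,4,31,0,0,9,69,1,22
14,control,,6,2,4,58,0,0,1,17,5,83,0,
15,control,,8,3,5,62,3,38,0,0,5,63,1,22
16,control,,7,6,1,66,3,43,0,0,4,57,1,33
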