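# Reference TPE-FLIM decay-parameter distributions (mean +/- SD) for dermal and
# epidermal cell classes, with the per-class cell counts used to assemble the
# 399-cell classification dataset. Lifetimes in ps, amp_ratio = a1/a2
# (dimensionless), intensity in photons/mW.
# group_label: 0 = M1 macrophage, 1 = M2 macrophage, 2 = other dermal cell.
# The ex vivo / in vivo mast-cell rows are synthetic stand-ins: their counts are
# real but their parameter distributions reuse the in vitro resting/activated
# mast-cell values (no separate printed distributions exist for them).
class_name,group_label,environment,n_cells,tau1_mean,tau1_sd,tau2_mean,tau2_sd,taum_mean,taum_sd,amp_ratio_mean,amp_ratio_sd,intensity_mean,intensity_sd
monocyte-derived M1 macrophages,0,in_vitro,21,163,50,1209,161,479,106,2.4,0.6,600,100
monocyte-derived M2 macrophages,1,in_vitro,27,417,134,2305,194,1185,170,2.3,0.5,500,100
isolated dermal M1 macrophages,0,in_vitro,34,225,84,1289,278,461,175,4.8,3.4,3000,500
isolated dermal M2 macrophages,1,in_vitro,28,807,250,2352,229,1281,155,2.2,1.1,800,200
M1 macrophages (CD68),0,ex_vivo,8,190,38,1504,133,458,50,4.1,0.7,3000,500
M2 macrophages (CD163),1,ex_vivo,12,498,129,2267,155,1369,201,1.1,0.4,700,300
M1 macrophages,0,in_vivo,40,196,40,1698,172,477,105,5.0,2.8,686,165
phagocytosing M1 macrophages,0,in_vivo,2,105,10,1272,89,195,44,14.7,4.5,1100,150
M2 macrophages,1,in_vivo,28,442,54,2458,90,1407,60,1.2,0.2,360,155
resting mast cells,2,in_vitro,45,533,266,2289,317,1248,287,1.5,0.5,1300,400
activated mast cells,2,in_vitro,14,288,130,1920,287,862,268,2.5,2.0,900,200
resting mast cells,2,ex_vivo,13,533,266,2289,317,1248,287,1.5,0.5,1300,400
activated mast cells,2,ex_vivo,4,288,130,1920,287,862,268,2.5,2.0,900,200
resting mast cells,2,in_vivo,63,533,266,2289,317,1248,287,1.5,0.5,1300,400
activated mast cells,2,in_vivo,19,288,130,1920,287,862,268,2.5,2.0,900,200
dendritic cells,2,in_vitro,14,434,188,2578,328,1265,180,1.6,0.2,538,258
fibroblasts,2,in_vitro,6,429,51,1983,137,921,81,0.5,0.1,469,137
neutrophils,2,in_vitro,21,714,250,1795,600,1074,109,1.5,0.5,500,115
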