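des_id,hba,hbd,ratio,tc_K,pc_bar,vc_cm3mol,omega,mw_gmol,ref
DES1,1-Ethyl-3-methylimidazolium,Ethylene glycol,2:1,670.98,36.65,355.99,0.666,118.44,47
DES2,1-Ethyl-3-methylimidazolium,Ethylene glycol,1:1,651.23,39.77,308.96,0.7476,104.35,47
DES3,1-Ethyl-3-methylimidazolium,Ethylene glycol,1:2,632.35,43.77,264.25,0.8293,90.25,47
DES4,Benzyl-tributyl-ammonium-chloride,Ethylene glycol,1:3,657.28,31.24,364.48,0.9659,124.54,48
DES5,Benzyl-tributyl-ammonium-chloride,Diethylene glycol,1:3,720.58,25.62,480.62,0.9994,157.57,48
DES6,Benzyl-tributyl-ammonium-chloride,Triethylene glycol,1:3,778.21,22.07,589.83,1.0507,190.61,48
DES7,Benzyl-tributyl-ammonium-chloride,Glycerol,1:3,749.11,25.67,433.69,1.3146,147.05,48
DES8,Benzyl-trimethyl-ammonium-chloride,Ethylene glycol,1:3,618.43,41.08,270.56,0.8745,92.98,48
DES9,Benzyl-trimethyl-ammonium-chloride,Diethylene glycol,1:3,678.15,31.88,377.22,0.908,126.01,48
DES10,Benzyl-trimethyl-ammonium-chloride,Triethylene glycol,1:3,733.31,26.6,478.88,0.9593,159.05,48
DES11,Benzyl-trimethyl-ammonium-chloride,Glycerol,1:3,708.07,32.89,333.89,1.2232,115.49,48
DES12,Benzyl-tripropyl-ammonium-chloride,Phenol,1:3,701.16,37.82,380.25,0.5152,138.05,49
DES13,Benzyl-tripropyl-ammonium-chloride,Ethylene glycol,1:3,644.1,33.78,334.18,0.9375,114.02,49
DES14,Benzyl-tripropyl-ammonium-chloride,Lactic acid,1:3,721.27,33.15,384.56,0.9166,135.02,49
DES15,Betaine,Glycerol,1:3,735.27,27.58,401.61,1.2862,98.36,49
DES16,Betaine,Lactic acid,1:2,668.5,44.09,281.96,0.7863,99.10,50
DES17,Betaine,Lactic acid,1:5,683.07,47.23,259.82,0.8755,94.59,50
DES18,Betaine,Levulinic acid,1:2,701.24,38.94,356.12,0.6195,116.46,50
DES19,Betaine,Lactic acid/water,1:1:1,637.98,61.84,206.94,0.5794,75.08,50
DES20,Choline-Chloride,Citric acid/water,2:1:6,659.71,92.43,146.46,0.5139,64.38,50
DES21,Choline-Chloride,Urea,1:2,644.44,49.54,254.37,0.6509,86.58,51
DES22,Choline-Chloride,Ethylene glycol,1:2,602,40.99,259.67,0.9155,87.92,51
DES23,Choline-Chloride,Glycerol,1:2,680.67,33.46,315.17,1.2254,107.93,51
DES24,Choline-Chloride,Fructose,2:1,742.22,27.03,424.87,1.2278,153.13,51
DES25,Choline-Chloride,Glucose,2:1,738.99,27.23,422.14,1.2163,153.13,51
DES26,Choline-Chloride,"1,2 propanediol",1:3,620.93,38.44,284.11,0.929,91.97,52
DES27,Choline-Chloride,Levulinic acid,1:2,702.19,35.4,376.78,0.7301,123.95,53
DES28,Choline-Chloride,Malonic acid,1:1,689.82,37.16,335.84,0.8577,121.84,54
DES29,Choline-Chloride,Glutaric acid,1:1,713.43,32.24,397.17,0.8782,135.87,54
DES30,Choline-Chloride,Oxalic acid,1:1,676.24,40.44,303.06,0.8531,114.83,55
DES31,Dodecanoic,Octanoic acid,1:3,737.07,24.71,559.27,0.7649,158.24,56
DES32,Dodecanoic,Decanoic acid,1:2,773.88,21.55,656.4,0.8307,181.61,56
DES33,Menthol,Octanoic acid,1:1,717.72,28.79,493.39,0.6173,150.24,56
DES34,Menthol,Decanoic acid,1:1,739.17,26.26,549.11,0.6568,164.27,56
DES35,Menthol,Salicylic acid,4:1,744.23,33.56,445.77,0.5733,152.64,57
DES36,Menthol,Ethylene glycol,1:1,654.33,38.54,319.91,0.751,109.17,57
DES37,Proline,Levulinic acid,1:2,745.61,42.88,333.41,0.7044,115.79,50
DES38,Proline,Lactic acid,1:1,721.95,48.54,272.6,0.8243,102.61,50
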