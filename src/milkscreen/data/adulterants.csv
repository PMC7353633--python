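code,category,nitrogen_fraction,protein_fraction,solids_fraction,molar_mass,dissociation_count
WMP,protein_rich,0,0.26,0.97,0,0
SMP,protein_rich,0,0.34,0.97,0,0
WPI,protein_rich,0,0.90,0.95,0,0
PEA,protein_rich,0,0.80,0.95,0,0
SOY,protein_rich,0,0.90,0.95,0,0
URE,nitrogen,0.4663,0,1.0,60.06,1
MLM,nitrogen,0.6664,0,1.0,126.12,1
AS,nitrogen,0.2120,0,1.0,132.14,3
AC,nitrogen,0.2618,0,1.0,53.49,2
DIC,nitrogen,0.6664,0,1.0,84.08,1
SU,carbohydrate,0,0,1.0,342.30,1
GLU,carbohydrate,0,0,1.0,180.16,1
ST,carbohydrate,0,0,1.0,0,0
LAC,carbohydrate,0,0,1.0,342.30,1
FRU,carbohydrate,0,0,1.0,180.16,1
MD,carbohydrate,0,0,1.0,0,0
AR,carbohydrate,0,0,1.0,0,0
CIT,preservative,0,0,1.0,258.07,4
CAR,preservative,0,0,1.0,105.99,3
BIC,preservative,0,0,1.0,84.01,2
HYD,preservative,0,0,1.0,40.00,2
FMD,preservative,0,0,1.0,30.03,1
PX,preservative,0,0,1.0,34.01,1
WATER,water,0,0,0.0,18.02,0
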