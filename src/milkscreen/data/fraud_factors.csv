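factor_id,group,description,E,N,NW,NE
1,opportunity_motivation,Available technology for milk adulteration,49,46,71,66
2,opportunity_motivation,Detectability of adulteration,51,56,35,58
3,opportunity_motivation,Accessibility to production activities,53,49,57,63
4,opportunity_motivation,Relationships within the supply chain,47,61,39,36
5,opportunity_motivation,Valuable components/attributes,38,62,39,42
6,opportunity_motivation,Farmer's financial pressure imposed by the company,40,61,40,45
7,opportunity_motivation,Level of competition,73,41,73,53
8,opportunity_motivation,Price difference due to regulatory differences,62,47,67,48
9,control,Application of integrity screening of employees,51,46,70,63
10,control,Strictness of the ethical code of conduct,45,48,70,61
11,control,Support of a whistle-blowing system,62,47,69,48
12,control,Specificity of the national food policy,70,48,55,49
13,control,Availability of a fraud contingency plan,62,45,65,61
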