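label_type	family	field	key	template	extractable
sex	explicit	characteristics	Sex	{sex}	1
sex	explicit	characteristics	gender	{sex}	1
sex	abbreviated	characteristics	sex	{sex_abbr}	1
sex	abbreviated	description		sex: {sex_abbr}	1
sex	numeric	characteristics	gender	{sex_01}	1
sex	implicit	title		patient ({age_int}, {sex_abbr}, non-smoker)	0
age	explicit	characteristics	Age	{age_value} {age_unit}	1
age	explicit	description		age: {age_value} {age_unit_abbr}	1
age	abbreviated	characteristics	age	{age_int}	1
age	unit_in_key	characteristics	age ({age_unit_abbr})	{age_value}	1
age	misspelled	characteristics	Age	{age_value} {age_unit_typo}	0
age	implicit	title		patient ({age_int}, {sex_abbr}, non-smoker)	0
tissue	explicit	characteristics	Tissue	{tissue_name}	1
tissue	synonym	characteristics	Tissue	{tissue_synonym}	1
tissue	source	source_name		{tissue_name} biopsy	1
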