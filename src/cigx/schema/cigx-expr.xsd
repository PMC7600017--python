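<?xml version="1.0" encoding="UTF-8"?>
<!-- Expression portion of the cigx guideline dialect (namespace urn:cigx:1).

     A condition is one element drawn from the "expr" group: logical
     connectives (and/or with >=2 operands, not with 1), the constants
     true/false, six comparison operators pairing a symbol with a value or a
     second symbol, set membership (in-set, possibly empty), interval
     membership (in-range, at least one bound - enforced by the loader) and
     an explicit paren wrapper. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:c="urn:cigx:1"
           targetNamespace="urn:cigx:1"
           elementFormDefault="qualified"
           attributeFormDefault="unqualified">

  <xs:simpleType name="valueKind">
    <xs:restriction base="xs:string">
      <xs:enumeration value="boolean"/>
      <xs:enumeration value="integer"/>
      <xs:enumeration value="decimal"/>
      <xs:enumeration value="text"/>
      <xs:enumeration value="date"/>
      <xs:enumeration value="datetime"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="semanticPath">
    <xs:restriction base="xs:string">
      <xs:pattern value="[A-Za-z_][A-Za-z0-9_]*(/[A-Za-z_][A-Za-z0-9_]*)*"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="valueType">
    <xs:simpleContent>
      <xs:extension base="xs:string">
        <xs:attribute name="type" type="c:valueKind" use="required"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

  <xs:complexType name="symbolType">
    <xs:attribute name="path" type="c:semanticPath" use="required"/>
  </xs:complexType>

  <xs:group name="expr">
    <xs:choice>
      <xs:element name="and" type="c:naryType"/>
      <xs:element name="or" type="c:naryType"/>
      <xs:element name="not" type="c:unaryType"/>
      <xs:element name="paren" type="c:unaryType"/>
      <xs:element name="true" type="c:emptyType"/>
      <xs:element name="false" type="c:emptyType"/>
      <xs:element name="eq" type="c:comparisonType"/>
      <xs:element name="ne" type="c:comparisonType"/>
      <xs:element name="gt" type="c:comparisonType"/>
      <xs:element name="lt" type="c:comparisonType"/>
      <xs:element name="ge" type="c:comparisonType"/>
      <xs:element name="le" type="c:comparisonType"/>
      <xs:element name="in-set" type="c:inSetType"/>
      <xs:element name="in-range" type="c:inRangeType"/>
    </xs:choice>
  </xs:group>

  <xs:complexType name="emptyType"/>

  <xs:complexType name="naryType">
    <xs:group ref="c:expr" minOccurs="2" maxOccurs="unbounded"/>
  </xs:complexType>

  <xs:complexType name="unaryType">
    <xs:group ref="c:expr"/>
  </xs:complexType>

  <xs:complexType name="comparisonType">
    <xs:sequence>
      <xs:element name="symbol" type="c:symbolType"/>
      <xs:choice>
        <xs:element name="value" type="c:valueType"/>
        <xs:element name="symbol" type="c:symbolType"/>
      </xs:choice>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="inSetType">
    <xs:sequence>
      <xs:element name="value" type="c:valueType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="symbol" type="c:semanticPath" use="required"/>
  </xs:complexType>

  <xs:complexType name="inRangeType">
    <xs:attribute name="symbol" type="c:semanticPath" use="required"/>
    <xs:attribute name="type" type="c:valueKind" use="required"/>
    <xs:attribute name="lower" type="xs:string"/>
    <xs:attribute name="upper" type="xs:string"/>
    <xs:attribute name="lower-inclusive" type="xs:boolean" default="true"/>
    <xs:attribute name="upper-inclusive" type="xs:boolean" default="true"/>
  </xs:complexType>

  <!-- Global wrapper so a bare expression fragment can be validated on its
       own; inside documents the same element carries a goal's conditions. -->
  <xs:element name="conditions" type="c:unaryType"/>

</xs:schema>
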